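"""Converted-genome alignment and per-cytosine C/T counting.

Deaminated reads are mapped in a C-to-T collapsed ("three-letter") alphabet:
both the read and the reference are converted C->T, which makes converted and
unconverted cytosines indistinguishable during matching.  The reference is
indexed on both strands (plus strand directly; minus strand via reverse
complement then C->T), reads are anchored with an exact seed at the read start
and extended with a bounded-mismatch comparison, and reads with equally good
hits at more than one locus are flagged non-unique and excluded downstream.

The pileup then counts, per reference cytosine and strand, reads showing C
(candidate 5hmC, N_C) versus T (converted C or 5mC, N_T) in the original
(unconverted) read sequence.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd

from .core import A, C, G, T, COMP_CODE, ReadSet, ReferenceSet, encode

__all__ = [
    "convert_for_alignment",
    "align_reads",
    "pileup",
    "Alignment",
    "read_site_counts",
    "write_site_counts",
    "write_fraction_bedgraph",
]

SEED_LEN = 20

ALIGN_COLUMNS = [
    "read_index", "read_id", "contig", "start", "strand",
    "matched", "unique", "n_mismatch",
]

Alignment = namedtuple("Alignment", ALIGN_COLUMNS)

_C2T = str.maketrans("Cc", "Tt")
_G2A = str.maketrans("Gg", "Aa")

COUNT_COLUMNS = [
    "contig", "pos0", "strand", "context5p", "context3p", "N_C", "N_T", "N_other",
]

_PAD = 255  # sentinel byte in the concatenated converted reference


def convert_for_alignment(sequence: str, mode: str) -> str:
    """Collapse the alphabet for converted-space matching.

    mode "C2T" replaces every C with T (plus-strand space); mode "G2A"
    replaces every G with A (the complementary collapse).  Length preserved.
    """
    allowed = set("ACGTNacgtn")
    bad = set(sequence) - allowed
    if bad:
        raise ValueError(f"invalid symbols in sequence: {sorted(bad)}")
    if mode == "C2T":
        return sequence.translate(_C2T)
    if mode == "G2A":
        return sequence.translate(_G2A)
    raise ValueError(f"mode must be 'C2T' or 'G2A', got {mode!r}")


class _ConvertedIndex:
    """Exact-seed index over the C->T-converted reference, both strands.

    Segments (contig x strand) are concatenated with sentinel padding; seeds
    are 2-bit-packed ``seed_len``-mers located by binary search in a sorted
    code array.  Minus-strand segments hold the converted reverse complement;
    local molecule coordinates are mapped back to plus-strand starts.
    """

    def __init__(self, ref: ReferenceSet, seed_len: int = SEED_LEN, pad: int = 200):
        self.ref = ref
        self.seed_len = seed_len
        self.contig_names = list(ref.contigs)
        seg_arrays = []
        seg_meta = []  # (contig_idx, strand, length, offset)
        offset = 0
        kcodes_parts = []
        kpos_parts = []
        for ci, name in enumerate(self.contig_names):
            codes = ref.encoded(name)
            for strand in "+-":
                arr = codes if strand == "+" else COMP_CODE[codes[::-1]]
                conv = arr.copy()
                conv[conv == C] = T
                seg_meta.append((ci, strand, conv.size, offset))
                seg_arrays.append(conv)
                seg_arrays.append(np.full(pad, _PAD, dtype=np.uint8))
                if conv.size >= seed_len:
                    k = _kmer_codes(conv, seed_len)
                    kcodes_parts.append(k)
                    kpos_parts.append(np.arange(k.size, dtype=np.int64) + offset)
                offset += conv.size + pad
        self.cat = np.concatenate(seg_arrays)
        self.seg_meta = seg_meta
        self.seg_offsets = np.array([m[3] for m in seg_meta], dtype=np.int64)
        self.seg_lengths = np.array([m[2] for m in seg_meta], dtype=np.int64)
        kcodes = np.concatenate(kcodes_parts) if kcodes_parts else np.empty(0, np.uint64)
        kpos = np.concatenate(kpos_parts) if kpos_parts else np.empty(0, np.int64)
        order = np.argsort(kcodes, kind="stable")
        self.kcodes_sorted = kcodes[order]
        self.kpos_sorted = kpos[order]

    def lookup(self, seed_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.kcodes_sorted, seed_codes, side="left")
        hi = np.searchsorted(self.kcodes_sorted, seed_codes, side="right")
        return lo, hi

    def segment_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.seg_offsets, gpos, side="right") - 1


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit rolling pack of all k-mers (N hashed as A; verified later)."""
    h = (codes & 3).astype(np.uint64)
    n = codes.size - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | h[j:j + n]
    return out


def _read_matrix(seqs: list[str], idxs: np.ndarray) -> np.ndarray:
    """uint8 code matrix for the (equal-length) reads at ``idxs``."""
    joined = "".join(seqs[i] for i in idxs)
    flat = encode(joined)
    return flat.reshape(len(idxs), -1)


def align_reads(
    reads: ReadSet,
    ref: ReferenceSet,
    max_mismatch: int = 2,
    seed_len: int = SEED_LEN,
    _index: _ConvertedIndex | None = None,
) -> pd.DataFrame:
    """Align converted reads against both converted reference strands.

    Returns a DataFrame with one row per read: read_index, read_id, contig,
    start (0-based plus-strand), strand, matched, unique, n_mismatch.
    Mismatches are counted in the converted (three-letter) space.  Reads whose
    best score is attained at more than one locus get ``unique=False``; reads
    with no hit within ``max_mismatch`` get ``matched=False``.
    """
    n = len(reads)
    index = _index if _index is not None else _ConvertedIndex(ref, seed_len)
    res_contig = np.full(n, "", dtype=object)
    res_start = np.full(n, -1, dtype=np.int64)
    res_strand = np.full(n, ".", dtype=object)
    res_matched = np.zeros(n, dtype=bool)
    res_unique = np.zeros(n, dtype=bool)
    res_mm = np.full(n, -1, dtype=np.int64)

    lengths = np.array([len(s) for s in reads.sequences], dtype=np.int64)
    for read_len in np.unique(lengths):
        if read_len < seed_len:
            continue  # too short to anchor; stays unmatched
        grp = np.flatnonzero(lengths == read_len)
        mat = _read_matrix(reads.sequences, grp)
        conv = mat.copy()
        conv[conv == C] = T
        pending = np.arange(grp.size)
        best_mm = np.full(grp.size, 10 ** 6, dtype=np.int64)
        best_pos = np.full(grp.size, -1, dtype=np.int64)
        n_best = np.zeros(grp.size, dtype=np.int64)
        # primary seed at the read start; one rescue seed one seed-length in
        for seed_off in (0, int(seed_len)) :
            if pending.size == 0 or seed_off + seed_len > read_len:
                break
            sub = conv[pending]
            seeds = _kmer_codes_matrix(sub[:, seed_off:seed_off + seed_len])
            lo, hi = index.lookup(seeds)
            cnt = hi - lo
            _score_candidates(
                index, conv, pending, lo, cnt, seed_off, int(read_len),
                best_mm, best_pos, n_best,
            )
            pending = pending[cnt == 0]
        ok = best_mm <= max_mismatch
        res_matched[grp[ok]] = True
        res_mm[grp] = np.where(best_mm < 10 ** 6, best_mm, -1)
        uniq = ok & (n_best == 1)
        res_unique[grp[uniq]] = True
        hit = np.flatnonzero(ok)
        if hit.size:
            seg = index.segment_of(best_pos[hit])
            local = best_pos[hit] - index.seg_offsets[seg]
            for i, s, lc in zip(grp[hit], seg, local):
                ci, strand, seg_len, _ = index.seg_meta[s]
                name = index.contig_names[ci]
                start = int(lc) if strand == "+" else int(seg_len - lc - read_len)
                res_contig[i] = name
                res_start[i] = start
                res_strand[i] = strand
    return pd.DataFrame(
        {
            "read_index": np.arange(n),
            "read_id": reads.names,
            "contig": res_contig,
            "start": res_start,
            "strand": res_strand,
            "matched": res_matched,
            "unique": res_unique,
            "n_mismatch": res_mm,
        }
    )


def _kmer_codes_matrix(mat: np.ndarray) -> np.ndarray:
    h = (mat & 3).astype(np.uint64)
    out = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(mat.shape[1]):
        out = (out << np.uint64(2)) | h[:, j]
    return out


def _score_candidates(
    index: _ConvertedIndex,
    conv: np.ndarray,
    pending: np.ndarray,
    lo: np.ndarray,
    cnt: np.ndarray,
    seed_off: int,
    read_len: int,
    best_mm: np.ndarray,
    best_pos: np.ndarray,
    n_best: np.ndarray,
    chunk: int = 250_000,
) -> None:
    """Score every candidate locus for the pending reads and fold the results
    into the running per-read best (min mismatches, locus, tie count)."""
    total = int(cnt.sum())
    if total == 0:
        return
    starts_cum = np.concatenate(([0], np.cumsum(cnt)[:-1]))
    flat = np.repeat(lo - starts_cum, cnt) + np.arange(total)
    pair_read = np.repeat(np.arange(pending.size), cnt)
    pair_gpos = index.kpos_sorted[flat] - seed_off  # candidate read start, global
    seg = index.segment_of(pair_gpos)
    local = pair_gpos - index.seg_offsets[seg]
    in_bounds = (local >= 0) & (local + read_len <= index.seg_lengths[seg])
    mm = np.full(total, 10 ** 6, dtype=np.int64)
    ar = np.arange(read_len)
    for s in range(0, total, chunk):
        e = min(s + chunk, total)
        sel = np.flatnonzero(in_bounds[s:e]) + s
        if sel.size == 0:
            continue
        ref_block = index.cat[pair_gpos[sel][:, None] + ar]
        read_block = conv[pending[pair_read[sel]]]
        mm[sel] = (ref_block != read_block).sum(axis=1)
    # fold into running best per read
    for r, g, m in zip(pair_read, pair_gpos, mm):
        i = pending[r]
        if m < best_mm[i]:
            best_mm[i] = m
            best_pos[i] = g
            n_best[i] = 1
        elif m == best_mm[i] and m < 10 ** 6 and g != best_pos[i]:
            n_best[i] += 1


def pileup(alignments: pd.DataFrame, reads: ReadSet, ref: ReferenceSet) -> pd.DataFrame:
    """Per-cytosine strand-aware C/T counts from matched, unique alignments.

    For each plus-strand reference C covered by a plus-strand alignment, a
    read base C increments N_C, T increments N_T, anything else N_other; the
    minus strand is symmetric on reference G with plus-projected read bases
    G (retained C) and A (converted).  Rows with zero coverage are omitted.
    """
    use = alignments[alignments.matched & alignments.unique]
    counts: dict[str, dict[str, np.ndarray]] = {}
    lengths = ref.lengths()
    for contig in ref.contigs:
        L = lengths[contig]
        counts[contig] = {
            s: np.zeros((3, L), dtype=np.int64) for s in "+-"
        }
    read_lens = np.array([len(s) for s in reads.sequences], dtype=np.int64)
    for (contig, strand), sub in use.groupby(["contig", "strand"], sort=False):
        L = lengths[contig]
        ref_codes = ref.encoded(contig)
        starts_all = sub.start.to_numpy()
        ridx_all = sub.read_index.to_numpy()
        if np.any(starts_all < 0) or np.any(starts_all + read_lens[ridx_all] > L):
            raise ValueError(f"alignment out of bounds on contig {contig!r}")
        acc = counts[contig][strand]
        for rl in np.unique(read_lens[ridx_all]):
            pick = read_lens[ridx_all] == rl
            starts = starts_all[pick]
            mat = _read_matrix(reads.sequences, ridx_all[pick])
            idx = starts[:, None] + np.arange(rl)
            if strand == "+":
                site = (ref_codes == C)[idx]
                base = mat
                code_c, code_t = C, T
            else:
                site = (ref_codes == G)[idx]
                base = COMP_CODE[mat][:, ::-1]  # plus-strand projection
                code_c, code_t = G, A
            np.add.at(acc[0], idx[site & (base == code_c)], 1)
            np.add.at(acc[1], idx[site & (base == code_t)], 1)
            np.add.at(acc[2], idx[site & (base != code_c) & (base != code_t)], 1)
    rows = []
    comp = dict(zip("ACGTN", "TGCAN"))
    for contig in ref.contigs:
        seq = ref.contigs[contig]
        L = lengths[contig]
        for strand in "+-":
            acc = counts[contig][strand]
            covered = np.flatnonzero(acc.sum(axis=0) > 0)
            for p in covered:
                p = int(p)
                if strand == "+":
                    c5 = seq[p - 1] if p > 0 else "N"
                    c3 = seq[p + 1] if p + 1 < L else "N"
                else:
                    c5 = comp[seq[p + 1]] if p + 1 < L else "N"
                    c3 = comp[seq[p - 1]] if p > 0 else "N"
                rows.append(
                    (contig, p, strand, c5, c3,
                     int(acc[0, p]), int(acc[1, p]), int(acc[2, p]))
                )
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    order = {name: i for i, name in enumerate(ref.contigs)}
    df = df.sort_values(
        ["contig", "pos0", "strand"],
        key=lambda col: col.map(order) if col.name == "contig" else col,
        kind="stable",
    ).reset_index(drop=True)
    return df


def write_site_counts(df: pd.DataFrame, path) -> None:
    """Write a site count table as TSV with header."""
    df.to_csv(path, sep="\t", index=False)


def read_site_counts(path) -> pd.DataFrame:
    """Read a site count table written by :func:`write_site_counts` (or an
    externally produced table in the same dialect)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "strand": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df[COUNT_COLUMNS]


def write_fraction_bedgraph(df: pd.DataFrame, path, strand: str | None = None) -> None:
    """bedGraph of the raw per-site C fraction N_C/(N_C+N_T) (depth > 0 rows).

    bedGraph is unstranded; pass ``strand`` to restrict to one strand.
    """
    sub = df if strand is None else df[df.strand == strand]
    depth = sub.N_C + sub.N_T
    sub = sub[depth > 0]
    frac = sub.N_C / (sub.N_C + sub.N_T)
    out = pd.DataFrame(
        {
            "contig": sub.contig,
            "start": sub.pos0,
            "end": sub.pos0 + 1,
            "value": frac.round(6),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
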