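"""Synthetic data generation.

Everything the analysis consumes can be generated here with the statistical
structure the method assumes: a CpG-depleted genome carrying 5mC/5hmC almost
exclusively at CpG sites, unmodified and uniformly modified spike-in contigs,
deamination-converted sequencing reads with a truth sidecar, per-molecule
colony and mixture read sets, and Michaelis-Menten kinetic data points.

Deamination acts once per molecule, per cytosine, with a probability given by
the enzyme model for the cytosine's modification state and 5' neighbor; a
deaminated cytosine is emitted as T.  PCR amplification, adapters, paired-end
structure and base qualities are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    A, C, G, T,
    COMP_CODE,
    DNA_BASES,
    DeaminationModel,
    ModificationMap,
    ReadSet,
    ReferenceSet,
    decode,
    encode,
)

__all__ = [
    "build_reference",
    "default_spike_ins",
    "plant_modifications",
    "simulate_reads",
    "simulate_colonies",
    "simulate_mixture",
    "simulate_kinetics",
    "KineticPoint",
    "KineticAssay",
    "KINETIC_DEFAULTS",
]

_STATE_CODE = {"unmodified": 0, "all-5mC": 1, "all-5hmC": 2}


# ---------------------------------------------------------------------------
# reference construction


def _markov_sequence(rng: np.random.Generator, length: int, gc_fraction: float,
                     cpg_enrichment: float) -> str:
    """First-order Markov DNA where the C->G transition probability is scaled
    by ``cpg_enrichment`` relative to the independent base frequency (obs/exp
    CpG ratio); all other transitions follow the base composition."""
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    base = [p_at, p_gc, p_gc, p_at]  # A C G T
    # row after C: G scaled, others renormalized
    pg = min(cpg_enrichment * p_gc, 0.95)
    rest = 1.0 - pg
    norm = base[A] + base[C] + base[T]
    after_c = [base[A] * rest / norm, base[C] * rest / norm, pg, base[T] * rest / norm]

    def cum3(row):
        return (row[0], row[0] + row[1], row[0] + row[1] + row[2])

    cum_base = cum3(base)
    cum_after_c = cum3(after_c)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    prev = -1
    for i in range(length):
        c0, c1, c2 = cum_after_c if prev == C else cum_base
        x = u[i]
        b = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        out[i] = b
        prev = b
    return decode(out)


def build_reference(
    seed: int,
    chrom_specs: list[tuple[str, int]],
    gc_fraction: float = 0.42,
    cpg_enrichment: float = 0.25,
    spike_ins: list[tuple[str, str, str]] | tuple = (),
) -> ReferenceSet:
    """Generate a synthetic genome plus optional spike-in contigs.

    Parameters
    ----------
    seed : RNG seed; generation is deterministic for a fixed seed.
    chrom_specs : (name, length) per genomic contig.
    gc_fraction : overall G+C fraction of generated chromosomes.
    cpg_enrichment : CpG obs/exp ratio; <1 depletes CpG dinucleotides as in
        mammalian genomes, >1 enriches them.
    spike_ins : (name, sequence, class) triplets appended verbatim, with class
        one of "unmodified", "all-5mC", "all-5hmC".
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    if cpg_enrichment <= 0:
        raise ValueError("cpg_enrichment must be > 0")
    for _, length in chrom_specs:
        if length <= 0:
            raise ValueError("chromosome lengths must be > 0")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for name, length in chrom_specs:
        pairs.append((name, _markov_sequence(rng, length, gc_fraction, cpg_enrichment)))
    labels: dict[str, str] = {name: "genomic" for name, _ in chrom_specs}
    for name, seq, cls in spike_ins:
        if cls not in ("unmodified", "all-5mC", "all-5hmC"):
            raise ValueError(f"unknown spike-in class {cls!r}")
        pairs.append((name, seq))
        labels[name] = cls
    return ReferenceSet.from_pairs(pairs, labels)


def default_spike_ins(seed: int = 20230) -> list[tuple[str, str, str]]:
    """Default spike-in trio: a lambda-phage-like fully unmodified contig and
    two uniformly modified amplicons (all-5mC, all-5hmC).  Lengths are small
    relative to a genomic contig, emulating the ~0.1% spike-in mass."""
    rng = np.random.default_rng(seed)
    out = []
    for name, length, cls in [
        ("lambda_spike", 3000, "unmodified"),
        ("spike_5mC", 1500, "all-5mC"),
        ("spike_5hmC", 1500, "all-5hmC"),
    ]:
        seq = decode(rng.integers(0, 4, size=length).astype(np.uint8))
        out.append((name, seq, cls))
    return out


# ---------------------------------------------------------------------------
# modification planting


def plant_modifications(
    ref: ReferenceSet,
    p_5mC_cpg: float = 0.75,
    p_5hmC_cpg: float = 0.10,
    p_5hmC_noncpg: float = 2e-4,
    seed: int = 0,
) -> ModificationMap:
    """Assign modification states to genomic cytosines.

    Each CpG cytosine (both strands, independently) becomes 5mC with
    ``p_5mC_cpg``, 5hmC with ``p_5hmC_cpg``, otherwise stays unmodified;
    non-CpG cytosines become 5hmC with ``p_5hmC_noncpg``.  Spike-in contigs
    are skipped — their state is their class label.
    """
    for p in (p_5mC_cpg, p_5hmC_cpg, p_5hmC_noncpg):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if p_5mC_cpg + p_5hmC_cpg > 1.0:
        raise ValueError("p_5mC_cpg + p_5hmC_cpg must be <= 1")
    rng = np.random.default_rng(seed)
    mods = ModificationMap()
    for contig in ref.genomic_contigs():
        codes = ref.encoded(contig)
        is_c = codes == C
        is_g = codes == G
        nxt_g = np.zeros_like(is_c)
        nxt_g[:-1] = codes[1:] == G
        prv_c = np.zeros_like(is_c)
        prv_c[1:] = codes[:-1] == C
        plan = [
            ("+", np.flatnonzero(is_c & nxt_g), np.flatnonzero(is_c & ~nxt_g)),
            ("-", np.flatnonzero(is_g & prv_c), np.flatnonzero(is_g & ~prv_c)),
        ]
        d_plus_minus = {}
        for strand, cpg_pos, noncpg_pos in plan:
            d: dict[int, str] = {}
            u = rng.random(cpg_pos.size)
            for pos in cpg_pos[u < p_5mC_cpg]:
                d[int(pos)] = "5mC"
            hmc = (u >= p_5mC_cpg) & (u < p_5mC_cpg + p_5hmC_cpg)
            for pos in cpg_pos[hmc]:
                d[int(pos)] = "5hmC"
            v = rng.random(noncpg_pos.size)
            for pos in noncpg_pos[v < p_5hmC_noncpg]:
                d[int(pos)] = "5hmC"
            d_plus_minus[strand] = d
        for strand, d in d_plus_minus.items():
            if d:
                mods.states[(contig, strand)] = d
    return mods


# ---------------------------------------------------------------------------
# read simulation


def _deamination_probs(
    mol: np.ndarray, state_codes_mol: np.ndarray, table: np.ndarray
) -> np.ndarray:
    """Per-position deamination probability along a molecule (0 at non-C)."""
    p = np.zeros(mol.size, dtype=float)
    c_idx = np.flatnonzero(mol == C)
    if c_idx.size == 0:
        return p
    nb = np.full(c_idx.size, 4, dtype=np.uint8)  # edge/unknown neighbor column
    inner = c_idx > 0
    nb[inner] = mol[c_idx[inner] - 1]
    nb[nb > 4] = 4
    p[c_idx] = table[state_codes_mol[c_idx], nb]
    return p


def _emit_reads(
    rng: np.random.Generator,
    mol: np.ndarray,
    p_arr: np.ndarray,
    starts: np.ndarray,
    read_len: int,
    seq_error: float,
) -> list[str]:
    """Draw deamination (then optional substitution error) for reads at
    ``starts`` along one molecule strand; returns read sequences."""
    if starts.size == 0:
        return []
    idx = starts[:, None] + np.arange(read_len)
    mat = mol[idx].copy()
    u = rng.random(mat.shape)
    mat[u < p_arr[idx]] = T
    if seq_error > 0:
        err = (rng.random(mat.shape) < seq_error) & (mat < 4)
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    b = mat.tobytes()
    from .core import _DECODE  # local import to keep the hot path tight

    txt = _DECODE[np.frombuffer(b, dtype=np.uint8)].tobytes().decode("ascii")
    return [txt[i * read_len:(i + 1) * read_len] for i in range(starts.size)]


def simulate_reads(
    ref: ReferenceSet,
    mods: ModificationMap,
    model: DeaminationModel,
    mean_depth: float = 10.0,
    read_len: int = 100,
    seed: int = 0,
    seq_error: float = 0.0,
) -> ReadSet:
    """Simulate deamination-converted single-end reads over all contigs.

    Per contig and strand, the number of reads is Poisson with mean
    ``mean_depth * L / read_len`` (≈ ``mean_depth`` coverage per strand) and
    read starts are uniform.  On each molecule every cytosine is deaminated
    independently with the model probability for its state and 5' neighbor;
    deaminated cytosines are emitted as T.  Spike-in contigs take their
    uniform class state; genomic contigs take states from ``mods``.
    """
    if read_len <= 0:
        raise ValueError("read_len must be > 0")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    min_len = min(ref.lengths().values())
    if read_len > min_len:
        raise ValueError(f"read_len {read_len} exceeds shortest contig ({min_len} bp)")
    if not 0.0 <= seq_error < 1.0:
        raise ValueError("seq_error must be in [0, 1)")
    rng = np.random.default_rng(seed)
    table = model.rate_table()
    names: list[str] = []
    seqs: list[str] = []
    truth_rows: list[tuple] = []
    counter = 0
    for contig, seq in ref.contigs.items():
        codes = encode(seq)
        L = codes.size
        label = ref.label(contig)
        for strand in "+-":
            if label == "genomic":
                state_plus = mods.state_codes(contig, strand, L)
            else:
                state_plus = np.full(L, _STATE_CODE[label], dtype=np.uint8)
            if strand == "+":
                mol = codes
                state_mol = state_plus
            else:
                mol = COMP_CODE[codes[::-1]]
                state_mol = state_plus[::-1]
            p_arr = _deamination_probs(mol, state_mol, table)
            n = rng.poisson(mean_depth * L / read_len)
            starts = rng.integers(0, L - read_len + 1, size=n)
            reads = _emit_reads(rng, mol, p_arr, starts, read_len, seq_error)
            for s_mol, r in zip(starts, reads):
                name = f"r{counter:08d}"
                counter += 1
                plus_start = int(s_mol) if strand == "+" else L - int(s_mol) - read_len
                names.append(name)
                seqs.append(r)
                truth_rows.append((name, contig, plus_start, strand))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "contig", "start", "strand"])
    return ReadSet(names, seqs, truth)


def simulate_colonies(
    substrate: str,
    state: str,
    model: DeaminationModel,
    n_colonies: int,
    seed: int = 0,
) -> ReadSet:
    """Colony sequencing: each colony is one full-length molecule of a
    uniformly modified substrate, deaminated independently per cytosine."""
    if not substrate:
        raise ValueError("substrate must be non-empty")
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    if state not in _STATE_CODE:
        raise ValueError(f"state must be one of {sorted(_STATE_CODE)}")
    rng = np.random.default_rng(seed)
    mol = encode(substrate)
    L = mol.size
    state_mol = np.full(L, _STATE_CODE[state], dtype=np.uint8)
    p_arr = _deamination_probs(mol, state_mol, model.rate_table())
    starts = np.zeros(n_colonies, dtype=np.int64)
    seqs = _emit_reads(rng, mol, p_arr, starts, L, 0.0)
    names = [f"colony{i:05d}" for i in range(n_colonies)]
    truth = pd.DataFrame(
        {"read_id": names, "contig": "substrate", "start": 0, "strand": "+"}
    )
    return ReadSet(names, seqs, truth)


def simulate_mixture(
    frac_5hmC: float,
    n_molecules: int,
    substrate: str,
    model: DeaminationModel,
    seed: int = 0,
) -> ReadSet:
    """Two-component mixture: each molecule is all-5hmC with probability
    ``frac_5hmC``, otherwise unmodified, then deaminated per cytosine."""
    if not 0.0 <= frac_5hmC <= 1.0:
        raise ValueError("frac_5hmC must be in [0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not substrate:
        raise ValueError("substrate must be non-empty")
    rng = np.random.default_rng(seed)
    mol = encode(substrate)
    L = mol.size
    table = model.rate_table()
    p_unmod = _deamination_probs(mol, np.zeros(L, dtype=np.uint8), table)
    p_hmc = _deamination_probs(mol, np.full(L, 2, dtype=np.uint8), table)
    is_hmc = rng.random(n_molecules) < frac_5hmC
    idx = np.broadcast_to(np.arange(L), (n_molecules, L))
    mat = np.broadcast_to(mol, (n_molecules, L)).copy()
    p_mat = np.where(is_hmc[:, None], p_hmc[idx[0]], p_unmod[idx[0]])
    u = rng.random(mat.shape)
    mat[u < p_mat] = T
    b = mat.tobytes()
    from .core import _DECODE

    txt = _DECODE[np.frombuffer(b, dtype=np.uint8)].tobytes().decode("ascii")
    seqs = [txt[i * L:(i + 1) * L] for i in range(n_molecules)]
    names = [f"mol{i:06d}" for i in range(n_molecules)]
    truth = pd.DataFrame(
        {
            "read_id": names,
            "contig": "substrate",
            "start": 0,
            "strand": "+",
            "state": np.where(is_hmc, "all-5hmC", "unmodified"),
        }
    )
    return ReadSet(names, seqs, truth)


# ---------------------------------------------------------------------------
# kinetics


@dataclass(frozen=True)
class KineticPoint:
    """One steady-state kinetic observation.

    ``frac_deaminated`` is the deaminated fraction I_D/(I_U + I_D), which
    equals rate * [E] * t under the rate definition used throughout.
    """

    substrate_conc: float  # uM
    enzyme_conc: float  # uM
    time: float  # min
    frac_deaminated: float

    def __post_init__(self) -> None:
        if self.substrate_conc <= 0 or self.enzyme_conc <= 0 or self.time <= 0:
            raise ValueError("concentrations and time must be > 0")
        if not 0.0 <= self.frac_deaminated <= 1.0:
            raise ValueError("frac_deaminated must be in [0, 1]")


@dataclass(frozen=True)
class KineticAssay:
    """Default kinetic parameters and assay design for one enzyme/substrate."""

    k_cat: float  # min^-1
    K_M: float  # uM
    enzyme_conc: float  # uM
    time: float  # min
    substrate_concs: tuple[float, ...]  # uM

    @property
    def efficiency(self) -> float:
        return self.k_cat / self.K_M


_S_HIGH = (0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5)
_S_LOW = (0.025, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0, 1.25)

#: Default kinetic parameterizations per (enzyme, substrate state).  k_cat and
#: K_M are chosen so k_cat/K_M equals the enzyme's catalytic efficiency
#: (uM^-1 min^-1): eA3A-v10 C 6.27, 5mC 3.90; wtA3A C 90.82, 5mC 22.45,
#: 5hmC 0.32.  eA3A-v10/5hmC has no entry: its activity on 5hmC is too low for
#: parameters to be measurable.  Assay conditions ([E], t, [S] range) follow
#: the steady-state designs for each substrate class.
KINETIC_DEFAULTS: dict[tuple[str, str], KineticAssay] = {
    ("eA3A-v10", "C"): KineticAssay(3.135, 0.5, 0.04, 5.0, _S_HIGH),
    ("eA3A-v10", "5mC"): KineticAssay(1.95, 0.5, 0.04, 5.0, _S_HIGH),
    ("wtA3A", "C"): KineticAssay(18.164, 0.2, 0.01, 5.0, _S_HIGH),
    ("wtA3A", "5mC"): KineticAssay(4.49, 0.2, 0.01, 5.0, _S_HIGH),
    ("wtA3A", "5hmC"): KineticAssay(0.16, 0.5, 1.0, 5.0, _S_LOW),
}


def simulate_kinetics(
    k_cat: float,
    K_M: float,
    enzyme_conc: float,
    time: float,
    s_list: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[KineticPoint]:
    """Generate deaminated-fraction observations from Michaelis-Menten truth.

    rate = k_cat * [S] / (K_M + [S]); frac = clamp(rate * [E] * t + noise, 0, 1)
    with Gaussian noise of sd ``noise_sd``.
    """
    if k_cat <= 0 or K_M <= 0 or enzyme_conc <= 0 or time <= 0:
        raise ValueError("k_cat, K_M, enzyme_conc and time must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s = np.asarray(s_list, dtype=float)
    if s.size == 0 or np.any(s <= 0):
        raise ValueError("all substrate concentrations must be > 0")
    rng = np.random.default_rng(seed)
    rate = k_cat * s / (K_M + s)
    frac = rate * enzyme_conc * time
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, size=s.size)
    frac = np.clip(frac, 0.0, 1.0)
    return [
        KineticPoint(float(si), enzyme_conc, time, float(fi))
        for si, fi in zip(s, frac)
    ]
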