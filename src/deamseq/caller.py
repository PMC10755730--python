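"""Base-resolution 5hmC calling.

Under the deamination readout, a read showing C at a cytosine site is evidence
of 5hmC; residual C can also arise from incomplete conversion at rate epsilon
(estimated from spike-ins).  Each site is tested against the null that its
N_C retained reads among depth N_C + N_T are non-conversion noise:

    p = P(X >= N_C),  X ~ Binomial(N_C + N_T, epsilon)

Multiple testing is controlled with Benjamini-Hochberg q-values over sites at
or above the depth floor; high-confidence sites satisfy depth >= 5 and
q < 0.01 by default.  Reads showing neither C nor T (N_other) are excluded
from the binomial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .core import ReferenceSet

__all__ = [
    "site_pvalue",
    "bh_adjust",
    "storey_adjust",
    "call_5hmc",
    "merge_symmetric_cpg",
    "write_calls_tsv",
    "write_highconf_bed",
]


def site_pvalue(n_c: int, n_t: int, epsilon: float) -> float:
    """Upper-tail binomial p-value P(X >= N_C) with X ~ Bin(N_C+N_T, epsilon)."""
    if n_c < 0 or n_t < 0:
        raise ValueError("counts must be >= 0")
    depth = n_c + n_t
    if depth < 1:
        raise ValueError("site depth (N_C + N_T) must be >= 1")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    return float(binom.sf(n_c - 1, depth, epsilon))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped to
    [0, 1], returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_adjust(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey-style q-values: BH scaled by the estimated null proportion
    pi0 = min(1, mean(p > lam) / (1 - lam))."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
    return np.clip(pi0 * bh_adjust(p), 0.0, 1.0)


def call_5hmc(
    counts: pd.DataFrame,
    epsilon: float,
    min_depth: int = 5,
    q_cutoff: float = 0.01,
    method: str = "bh",
) -> pd.DataFrame:
    """Per-site binomial 5hmC test with depth filtering and q-value control.

    Every row with depth >= 1 receives a 5hmC fraction N_C/(N_C+N_T) and a
    p-value; q-values are computed only over rows with depth >= ``min_depth``
    (others get NaN), and ``high_confidence`` requires both the depth floor
    and q < ``q_cutoff``.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if method not in ("bh", "storey"):
        raise ValueError("method must be 'bh' or 'storey'")
    out = counts.copy()
    n_c = out.N_C.to_numpy(dtype=np.int64)
    n_t = out.N_T.to_numpy(dtype=np.int64)
    depth = n_c + n_t
    frac = np.full(out.shape[0], np.nan)
    p = np.full(out.shape[0], np.nan)
    pos = depth > 0
    frac[pos] = n_c[pos] / depth[pos]
    p[pos] = binom.sf(n_c[pos] - 1, depth[pos], epsilon)
    out["depth"] = depth
    out["fraction"] = frac
    out["p_value"] = p
    q = np.full(out.shape[0], np.nan)
    testable = depth >= min_depth
    if testable.any():
        adjust = bh_adjust if method == "bh" else storey_adjust
        q[testable] = adjust(p[testable])
    out["q_value"] = q
    out["high_confidence"] = testable & (q < q_cutoff)
    return out


def merge_symmetric_cpg(counts: pd.DataFrame, ref: ReferenceSet) -> pd.DataFrame:
    """Optional post-step: pool the two strands of each symmetric CpG.

    A plus-strand C at position i and the minus-strand C at i+1 of a CpG
    dinucleotide report the same palindromic site; their counts are summed
    into one plus-strand row at position i (strand "cpg").  Non-CpG rows pass
    through unchanged.
    """
    from .core import C as _C, G as _G

    rows = []
    consumed = set()
    by_key = {(r.contig, int(r.pos0), r.strand): r for r in counts.itertuples()}
    for r in counts.itertuples():
        key = (r.contig, int(r.pos0), r.strand)
        if key in consumed:
            continue
        codes = ref.encoded(r.contig)
        p = int(r.pos0)
        if r.strand == "+" and p + 1 < codes.size and codes[p] == _C and codes[p + 1] == _G:
            mate = by_key.get((r.contig, p + 1, "-"))
            if mate is not None:
                consumed.add((r.contig, p + 1, "-"))
                rows.append(
                    (r.contig, p, "cpg", r.context5p, r.context3p,
                     r.N_C + mate.N_C, r.N_T + mate.N_T, r.N_other + mate.N_other)
                )
                continue
        if r.strand == "-" and p - 1 >= 0 and codes[p] == _G and codes[p - 1] == _C:
            if (r.contig, p - 1, "+") in by_key:
                # handled (or to be handled) from the plus row
                mate = by_key[(r.contig, p - 1, "+")]
                if (r.contig, p - 1, "+") not in consumed:
                    consumed.add(key)
                    rows.append(
                        (r.contig, p - 1, "cpg", mate.context5p, mate.context3p,
                         r.N_C + mate.N_C, r.N_T + mate.N_T, r.N_other + mate.N_other)
                    )
                    consumed.add((r.contig, p - 1, "+"))
                continue
        rows.append((r.contig, p, r.strand, r.context5p, r.context3p,
                     r.N_C, r.N_T, r.N_other))
    return pd.DataFrame(rows, columns=list(counts.columns[:8]))


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    """Full per-site table with fraction, p and q."""
    calls.to_csv(path, sep="\t", index=False)


def write_highconf_bed(calls: pd.DataFrame, path) -> None:
    """BED6 of high-confidence sites; score = round(1000 * fraction)."""
    hc = calls[calls.high_confidence]
    out = pd.DataFrame(
        {
            "contig": hc.contig,
            "start": hc.pos0,
            "end": hc.pos0 + 1,
            "name": "5hmC",
            "score": (1000 * hc.fraction).round().astype(int),
            "strand": hc.strand,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
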