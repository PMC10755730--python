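"""Genome-scale summaries of 5hmC calls.

Binned mean-fraction signal over tiling windows (for replicate / method
correlation), trinucleotide sequence-context classification (CpG / CHG /
CHH), distribution of calls over labeled genomic features, and a
strand-oriented metaprofile around transcription start sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import pearsonr

from .core import ReferenceSet, revcomp

__all__ = [
    "bin_signal",
    "correlate",
    "classify_context",
    "feature_distribution",
    "tss_metaprofile",
]

BIN_COLUMNS = ["contig", "bin_start", "bin_end", "mean_fraction", "n_sites"]


def bin_signal(
    calls: pd.DataFrame,
    contig_lengths: dict[str, int],
    bin_width: int = 10_000,
    high_conf_only: bool = True,
) -> pd.DataFrame:
    """Mean site fraction within fixed-width tiling bins.

    Bins tile each contig half-open at ``bin_width``; a bin's value is the
    mean ``fraction`` over the call rows falling in it (both strands pooled).
    With ``high_conf_only`` (default, mirroring high-confidence binned
    signal) only high-confidence rows contribute; otherwise every covered
    site's raw fraction contributes.  Empty bins carry ``n_sites=0`` and NaN
    mean.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sub = calls[calls.high_confidence.astype(bool)] if high_conf_only else calls
    sub = sub[np.isfinite(sub.fraction.astype(float))]
    rows = []
    for contig, L in contig_lengths.items():
        n_bins = (L + bin_width - 1) // bin_width
        sums = np.zeros(n_bins)
        ns = np.zeros(n_bins, dtype=np.int64)
        here = sub[sub.contig == contig]
        if len(here):
            b = (here.pos0.to_numpy() // bin_width).astype(np.int64)
            np.add.at(sums, b, here.fraction.to_numpy())
            np.add.at(ns, b, 1)
        with np.errstate(invalid="ignore"):
            means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        for i in range(n_bins):
            rows.append(
                (contig, i * bin_width, min((i + 1) * bin_width, L),
                 means[i], int(ns[i]))
            )
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def correlate(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> float:
    """Pearson r between two binned signals over bins non-empty in both.

    Empty bins are excluded pairwise (never zero-filled).  Requires at least
    3 shared non-empty bins and non-zero variance on both sides.
    """
    merged = bins_a.merge(
        bins_b, on=["contig", "bin_start"], suffixes=("_a", "_b")
    )
    merged = merged[(merged.n_sites_a > 0) & (merged.n_sites_b > 0)]
    if len(merged) < 3:
        raise ValueError("need at least 3 shared non-empty bins")
    x = merged.mean_fraction_a.to_numpy()
    y = merged.mean_fraction_b.to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Pearson r undefined")
    return float(pearsonr(x, y)[0])


def classify_context(ref: ReferenceSet, site: tuple[str, int, str]) -> str:
    """Sequence context (CpG / CHG / CHH) of a cytosine site, read 5'->3' on
    the site's strand; "NA" when fewer than 2 downstream bases exist."""
    contig, pos, strand = site
    seq = ref.contigs[contig]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"site ({contig!r},{pos},'+') is not a C")
        tri = seq[pos:pos + 3]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"site ({contig!r},{pos},'-') is not a C on the minus strand")
        tri = revcomp(seq[max(pos - 2, 0):pos + 1])
    else:
        raise ValueError(f"bad strand {strand!r}")
    if len(tri) < 2:
        return "NA"
    if tri[1] == "G":
        return "CpG"
    if len(tri) < 3:
        return "NA"
    return "CHG" if tri[2] == "G" else "CHH"


def feature_distribution(
    calls: pd.DataFrame,
    features: list[tuple[str, int, int, str]],
    priority: list[str] | None = None,
) -> dict[str, float]:
    """Proportion of high-confidence sites per feature label.

    ``features`` are half-open labeled intervals (contig, start, end, label);
    overlaps are resolved by ``priority`` order (labels not listed rank after
    listed ones, in first-seen order); unassigned sites are "intergenic".
    Proportions sum to 1 over all high-confidence sites.
    """
    trees: dict[str, IntervalTree] = {}
    seen_labels: list[str] = []
    for contig, start, end, label in features:
        if end <= start:
            raise ValueError(f"malformed interval {contig}:{start}-{end}")
        trees.setdefault(contig, IntervalTree()).addi(start, end, label)
        if label not in seen_labels:
            seen_labels.append(label)
    prio = list(priority or [])
    for lab in seen_labels:
        if lab not in prio:
            prio.append(lab)
    rank = {lab: i for i, lab in enumerate(prio)}
    hc = calls[calls.high_confidence.astype(bool)]
    if len(hc) == 0:
        raise ValueError("no high-confidence sites to distribute")
    tally: dict[str, int] = {}
    for contig, pos in zip(hc.contig, hc.pos0):
        tree = trees.get(contig)
        hits = tree[pos] if tree is not None else set()
        if hits:
            label = min((iv.data for iv in hits), key=lambda l: rank.get(l, len(rank)))
        else:
            label = "intergenic"
        tally[label] = tally.get(label, 0) + 1
    total = sum(tally.values())
    return {lab: n / total for lab, n in tally.items()}


def tss_metaprofile(
    calls: pd.DataFrame,
    tss_list: list[tuple[str, int, str]],
    window: int = 2000,
    bin_width: int = 100,
    high_conf_only: bool = True,
) -> pd.DataFrame:
    """Mean site fraction per strand-oriented offset bin around TSSs.

    Offsets are site_pos - tss_pos on plus-strand TSSs and tss_pos - site_pos
    on minus-strand TSSs (upstream negative), binned over [-window, window).
    Returns offset_start, offset_end, mean_fraction, n_sites per bin.
    """
    if not tss_list:
        raise ValueError("tss_list must be non-empty")
    if window <= 0 or bin_width <= 0 or window % bin_width != 0:
        raise ValueError("window must be a positive multiple of bin_width")
    sub = calls[calls.high_confidence.astype(bool)] if high_conf_only else calls
    sub = sub[np.isfinite(sub.fraction.astype(float))]
    n_bins = 2 * window // bin_width
    sums = np.zeros(n_bins)
    ns = np.zeros(n_bins, dtype=np.int64)
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, grp in sub.groupby("contig", sort=False):
        pos = grp.pos0.to_numpy()
        order = np.argsort(pos)
        by_contig[contig] = (pos[order], grp.fraction.to_numpy()[order])
    for contig, tpos, tstrand in tss_list:
        if tstrand not in "+-":
            raise ValueError(f"bad TSS strand {tstrand!r}")
        if contig not in by_contig:
            continue
        pos, frac = by_contig[contig]
        lo = np.searchsorted(pos, tpos - window, side="left")
        hi = np.searchsorted(pos, tpos + window, side="left")
        if hi <= lo:
            continue
        off = pos[lo:hi] - tpos
        if tstrand == "-":
            off = -off
        keep = (off >= -window) & (off < window)
        b = ((off[keep] + window) // bin_width).astype(np.int64)
        np.add.at(sums, b, frac[lo:hi][keep])
        np.add.at(ns, b, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    starts = np.arange(n_bins) * bin_width - window
    return pd.DataFrame(
        {
            "offset_start": starts,
            "offset_end": starts + bin_width,
            "mean_fraction": means,
            "n_sites": ns,
        }
    )
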