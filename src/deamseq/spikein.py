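"""Spike-in conversion-rate QC.

Spike-in contigs of known uniform modification state (an unmodified
lambda-like control, an all-5mC amplicon, an all-5hmC amplicon) calibrate the
deamination readout: the pooled T fraction over their cytosine sites measures
the C->T and 5mC->T conversion rates and the 5hmC->T leak.  The larger of the
two non-conversion rates (unmodified, all-5mC) becomes epsilon, the null
binomial success probability of the 5hmC caller — conservative, because the
caller must not report residual 5mC as 5hmC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClassConversion", "SpikeInReport", "estimate_conversion"]


@dataclass
class ClassConversion:
    """Pooled read-level counts and conversion rate for one spike-in class."""

    n_T: int
    n_C: int
    per_site_median: float  # diagnostic: median per-site T fraction

    @property
    def rate(self) -> float:
        return self.n_T / (self.n_T + self.n_C)


@dataclass
class SpikeInReport:
    per_class: dict[str, ClassConversion]
    epsilon: float | None
    context_table: pd.DataFrame = field(repr=False, default=None)

    def rate(self, cls: str) -> float:
        return self.per_class[cls].rate

    def to_json(self, path=None) -> str:
        d = {
            "classes": {
                cls: {"n_T": cc.n_T, "n_C": cc.n_C, "rate": cc.rate,
                      "per_site_median": cc.per_site_median}
                for cls, cc in self.per_class.items()
            },
            "epsilon": self.epsilon,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def estimate_conversion(
    counts: pd.DataFrame,
    labels: dict[str, str],
    classes: list[str] | None = None,
) -> SpikeInReport:
    """Estimate conversion rates from spike-in rows of a site count table.

    Parameters
    ----------
    counts : site count table (contig, pos0, strand, context5p, context3p,
        N_C, N_T, N_other).
    labels : contig -> spike-in class map ("unmodified", "all-5mC",
        "all-5hmC"; "genomic" entries are ignored).
    classes : classes to report; defaults to every non-genomic class present
        in ``labels``.  A requested class with zero C+T depth raises.

    Rates are pooled read-level proportions sum(N_T)/sum(N_C + N_T), not
    per-site averages; the per-site median T fraction is kept as a
    diagnostic.  epsilon is the larger non-conversion rate among the
    unmodified and all-5mC classes present.
    """
    if classes is None:
        classes = sorted({c for c in labels.values() if c != "genomic"})
    if not classes:
        raise ValueError("no spike-in classes requested")
    per_class: dict[str, ClassConversion] = {}
    ctx_rows = []
    for cls in classes:
        contigs = [name for name, c in labels.items() if c == cls]
        sub = counts[counts.contig.isin(contigs)]
        n_t = int(sub.N_T.sum())
        n_c = int(sub.N_C.sum())
        if n_t + n_c == 0:
            raise ValueError(f"spike-in class {cls!r} has zero C/T depth")
        depth = sub.N_T + sub.N_C
        site_frac = (sub.N_T[depth > 0] / depth[depth > 0]).to_numpy()
        median = float(np.median(site_frac)) if site_frac.size else float("nan")
        per_class[cls] = ClassConversion(n_t, n_c, median)
        for ctx, grp in sub.groupby("context5p"):
            d = int((grp.N_T + grp.N_C).sum())
            if d:
                ctx_rows.append((cls, ctx, int(grp.N_T.sum()), int(grp.N_C.sum()),
                                 grp.N_T.sum() / d))
    non_conv = [
        1.0 - per_class[c].rate for c in ("unmodified", "all-5mC") if c in per_class
    ]
    epsilon = max(non_conv) if non_conv else None
    ctx = pd.DataFrame(
        ctx_rows, columns=["class", "context5p", "n_T", "n_C", "rate"]
    )
    return SpikeInReport(per_class, epsilon, ctx)
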