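"""End-to-end conveniences tying the stages together.

These helpers run the standard chain simulate -> align -> pileup ->
spike-in QC -> binomial calling with one call each, for scripted analyses
and for replicate experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import align_reads, pileup
from .caller import call_5hmc
from .core import DeaminationModel, ModificationMap, ReadSet, ReferenceSet
from .simulate import (
    build_reference,
    default_spike_ins,
    plant_modifications,
    simulate_reads,
)
from .spikein import SpikeInReport, estimate_conversion

__all__ = ["analyze_reads", "simulate_genome_run", "GenomeRun"]


def analyze_reads(
    reads: ReadSet,
    ref: ReferenceSet,
    epsilon: float | None = None,
    min_depth: int = 5,
    q_cutoff: float = 0.01,
    max_mismatch: int = 2,
) -> tuple[pd.DataFrame, SpikeInReport | None, pd.DataFrame]:
    """Align, pile up, calibrate on spike-ins, and call 5hmC.

    If ``epsilon`` is None it is taken from the spike-in report (which then
    requires labeled spike-in contigs with coverage).  Returns
    (counts, spikein_report_or_None, calls).
    """
    alignments = align_reads(reads, ref, max_mismatch=max_mismatch)
    counts = pileup(alignments, reads, ref)
    report = None
    if epsilon is None:
        labels = {n: ref.label(n) for n in ref.contigs}
        report = estimate_conversion(counts, labels)
        if report.epsilon is None:
            raise ValueError("no unmodified/all-5mC spike-in to calibrate epsilon")
        epsilon = report.epsilon
    genomic = counts[
        counts.contig.map(lambda n: ref.label(n) == "genomic")
    ].reset_index(drop=True)
    calls = call_5hmc(genomic, epsilon, min_depth=min_depth, q_cutoff=q_cutoff)
    return counts, report, calls


class GenomeRun:
    """Bundle of one synthetic genome experiment (truth + analysis results)."""

    def __init__(self, ref, mods, reads, counts, report, calls):
        self.ref = ref
        self.mods = mods
        self.reads = reads
        self.counts = counts
        self.report = report
        self.calls = calls


def simulate_genome_run(
    seed: int,
    genome_length: int = 100_000,
    model: DeaminationModel | None = None,
    mean_depth: float = 10.0,
    read_len: int = 100,
    p_5mC_cpg: float = 0.75,
    p_5hmC_cpg: float = 0.10,
    p_5hmC_noncpg: float = 2e-4,
    ref: ReferenceSet | None = None,
    mods: ModificationMap | None = None,
) -> GenomeRun:
    """Generate (or reuse) a genome + truth map, simulate one sequencing run
    at ``mean_depth`` per strand, and analyze it end to end.

    Passing ``ref`` and ``mods`` reuses an existing truth (for replicate
    simulations of the same genome); ``seed`` then only drives the reads.
    """
    from .core import EA3A_V10

    model = model or EA3A_V10
    ss = np.random.SeedSequence(seed)
    s_ref, s_mod, s_reads = (int(x) for x in ss.generate_state(3) % (2 ** 31))
    if ref is None:
        ref = build_reference(
            s_ref,
            [("chr1", genome_length)],
            spike_ins=default_spike_ins(),
        )
    if mods is None:
        mods = plant_modifications(
            ref, p_5mC_cpg=p_5mC_cpg, p_5hmC_cpg=p_5hmC_cpg,
            p_5hmC_noncpg=p_5hmC_noncpg, seed=s_mod,
        )
    reads = simulate_reads(
        ref, mods, model, mean_depth=mean_depth, read_len=read_len, seed=s_reads
    )
    counts, report, calls = analyze_reads(reads, ref)
    return GenomeRun(ref, mods, reads, counts, report, calls)
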