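"""File format helpers: FASTA, FASTQ, BED truth maps, JSON run configs.

Coordinates are 0-based half-open in all BED/bedGraph outputs.
"""

from __future__ import annotations

import json

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DeaminationModel, ModificationMap, ReadSet, ReferenceSet

__all__ = [
    "write_fasta",
    "read_fasta",
    "read_fastq",
    "write_modification_bed",
    "read_modification_bed",
    "write_run_config",
]


def write_fasta(ref: ReferenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=ref.label(name))
        for name, seq in ref.contigs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path, labels: dict[str, str] | None = None) -> ReferenceSet:
    """Load a reference; spike-in labels may come from the ``labels`` map or,
    failing that, from the FASTA description field."""
    pairs = []
    desc_labels: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        pairs.append((rec.id, str(rec.seq).upper()))
        parts = rec.description.split(None, 1)
        if len(parts) == 2 and parts[1] in ("unmodified", "all-5mC", "all-5hmC", "genomic"):
            desc_labels[rec.id] = parts[1]
    return ReferenceSet.from_pairs(pairs, labels if labels is not None else desc_labels)


def read_fastq(path) -> ReadSet:
    names, seqs = [], []
    for rec in SeqIO.parse(path, "fastq"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    truth = pd.DataFrame({"read_id": names})
    return ReadSet(names, seqs, truth)


def write_modification_bed(mods: ModificationMap, path) -> None:
    """Truth map as BED6: contig, start, start+1, state, ".", strand."""
    df = mods.to_frame()
    out = pd.DataFrame(
        {
            "contig": df.contig,
            "start": df.pos0,
            "end": df.pos0 + 1,
            "name": df.state,
            "score": ".",
            "strand": df.strand,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_modification_bed(path) -> ModificationMap:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    mods = ModificationMap()
    for r in df.itertuples():
        mods.add(r.contig, int(r.start), r.strand, r.name)
    return mods


def write_run_config(path, model: DeaminationModel, **params) -> None:
    with open(path, "w") as fh:
        json.dump({"model": model.to_dict(), "params": params}, fh, indent=2)
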