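"""Shared domain types and sequence utilities.

The pipeline models a deaminase-conversion readout of cytosine modifications:
unmodified cytosine (C) and 5-methylcytosine (5mC) are deaminated by an
APOBEC3A-family enzyme and sequenced as T, while 5-hydroxymethylcytosine
(5hmC) resists deamination and is still read as C.  Everything downstream
(alignment in a C-to-T collapsed alphabet, per-site C/T counting, spike-in
calibration, binomial 5hmC calling) follows from that readout.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: Cytosine modification states, in internal code order (0, 1, 2).
STATES = ("C", "5mC", "5hmC")

#: Spike-in / contig classes.  Contigs without an explicit label are "genomic".
SPIKE_CLASSES = ("unmodified", "all-5mC", "all-5hmC", "genomic")

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> 2-bit code; N and anything else -> 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: complement in code space (A<->T, C<->G, N->N)
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

A, C, G, T, N = 0, 1, 2, 3, 4


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def _validate_dna(seq: str, name: str = "sequence", allow_n: bool = True) -> None:
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"{name} contains invalid symbols: {sorted(bad)}")


@dataclass
class DeaminationModel:
    """Per-base-state, per-5'-neighbor deamination probabilities for one enzyme.

    ``p_deaminate`` maps ``(state, neighbor)`` with state in :data:`STATES` and
    neighbor in ``"ACGT"`` (the 5' neighbor on the molecule's own strand) to the
    probability that a cytosine carrying that state is deaminated (and hence
    sequenced as T).  All 12 cells must be present.
    """

    enzyme_name: str
    p_deaminate: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for state in STATES:
            for nb in DNA_BASES:
                key = (state, nb)
                if key not in self.p_deaminate:
                    raise ValueError(f"missing deamination cell {key}")
                p = self.p_deaminate[key]
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability out of [0,1] at {key}: {p}")

    @classmethod
    def uniform(cls, enzyme_name: str, p_c: float, p_5mc: float, p_5hmc: float) -> "DeaminationModel":
        """Context-uniform model: one probability per modification state."""
        cells = {}
        for p, state in zip((p_c, p_5mc, p_5hmc), STATES):
            for nb in DNA_BASES:
                cells[(state, nb)] = p
        return cls(enzyme_name, cells)

    def rate_table(self) -> np.ndarray:
        """(3, 5) array of probabilities; rows follow :data:`STATES`, columns
        follow A,C,G,T plus a fifth column (unknown/edge neighbor) holding the
        row mean."""
        t = np.empty((3, 5), dtype=float)
        for i, state in enumerate(STATES):
            for j, nb in enumerate(DNA_BASES):
                t[i, j] = self.p_deaminate[(state, nb)]
            t[i, 4] = t[i, :4].mean()
        return t

    def state_mean(self, state: str) -> float:
        """Mean deamination probability of ``state`` across 5' contexts."""
        return float(np.mean([self.p_deaminate[(state, nb)] for nb in DNA_BASES]))

    def to_dict(self) -> dict:
        return {
            "enzyme_name": self.enzyme_name,
            "p_deaminate": {f"{s}|{nb}": p for (s, nb), p in self.p_deaminate.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeaminationModel":
        cells = {}
        for key, p in d["p_deaminate"].items():
            state, nb = key.split("|")
            cells[(state, nb)] = float(p)
        return cls(d["enzyme_name"], cells)


#: Engineered APOBEC3A variant: deaminates C and 5mC near-completely but
#: spares 5hmC (conversion 99.92% / 99.52% / 0.16%), context-uniform.
EA3A_V10 = DeaminationModel.uniform("eA3A-v10", 0.9992, 0.9952, 0.0016)

#: Wild-type APOBEC3A: deaminates C and 5mC completely and 5hmC substantially
#: (conversion 100.00% / 99.68% / 80.71%), context-uniform.
WT_A3A = DeaminationModel.uniform("wtA3A", 1.0000, 0.9968, 0.8071)

DEFAULT_MODELS = {"eA3A-v10": EA3A_V10, "wtA3A": WT_A3A}


@dataclass
class ReferenceSet:
    """A set of named contigs plus spike-in class labels.

    ``contigs`` maps contig name -> sequence (A/C/G/T[/N]); ``spike_in_labels``
    maps contig name -> class from :data:`SPIKE_CLASSES`.  Contigs absent from
    the label map are treated as "genomic".
    """

    contigs: dict[str, str]
    spike_in_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("ReferenceSet needs at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            _validate_dna(seq, f"contig {name!r}")
        for name, label in self.spike_in_labels.items():
            if name not in self.contigs:
                raise ValueError(f"spike-in label refers to unknown contig {name!r}")
            if label not in SPIKE_CLASSES:
                raise ValueError(f"unknown spike-in class {label!r}")

    @classmethod
    def from_pairs(
        cls,
        contigs: Iterable[tuple[str, str]],
        spike_in_labels: dict[str, str] | None = None,
    ) -> "ReferenceSet":
        """Build from (name, sequence) pairs, rejecting duplicate names."""
        d: dict[str, str] = {}
        for name, seq in contigs:
            if name in d:
                raise ValueError(f"duplicate contig name {name!r}")
            d[name] = seq
        return cls(d, dict(spike_in_labels or {}))

    def label(self, name: str) -> str:
        return self.spike_in_labels.get(name, "genomic")

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def encoded(self, name: str) -> np.ndarray:
        return encode(self.contigs[name])

    def genomic_contigs(self) -> list[str]:
        return [n for n in self.contigs if self.label(n) == "genomic"]


@dataclass
class ModificationMap:
    """Planted cytosine modifications, keyed by (contig, strand) -> {pos: state}.

    Positions are 0-based on the plus strand for both strands: a minus-strand
    cytosine sits at a plus-strand G position.  Positions absent from the map
    are unmodified C.
    """

    states: dict[tuple[str, str], dict[int, str]] = field(default_factory=dict)

    def add(self, contig: str, pos: int, strand: str, state: str) -> None:
        if state not in ("5mC", "5hmC"):
            raise ValueError(f"state must be 5mC or 5hmC, got {state!r}")
        if strand not in "+-":
            raise ValueError(f"bad strand {strand!r}")
        d = self.states.setdefault((contig, strand), {})
        if pos in d:
            raise ValueError(f"duplicate entry ({contig!r}, {pos}, {strand!r})")
        d[pos] = state

    def get(self, contig: str, pos: int, strand: str) -> str:
        """State at a site; 'C' (unmodified) when the site is not planted."""
        return self.states.get((contig, strand), {}).get(pos, "C")

    def __len__(self) -> int:
        return sum(len(d) for d in self.states.values())

    def iter_entries(self) -> Iterator[tuple[str, int, str, str]]:
        for (contig, strand), d in self.states.items():
            for pos, state in sorted(d.items()):
                yield contig, pos, strand, state

    def state_codes(self, contig: str, strand: str, length: int) -> np.ndarray:
        """Per-position state codes (0=C, 1=5mC, 2=5hmC) in plus coordinates."""
        arr = np.zeros(length, dtype=np.uint8)
        d = self.states.get((contig, strand))
        if d:
            pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
            codes = np.fromiter((STATES.index(s) for s in d.values()), dtype=np.uint8, count=len(d))
            arr[pos] = codes
        return arr

    def validate_against(self, ref: ReferenceSet) -> None:
        """Check every entry addresses a C (plus) or G (minus) reference base."""
        for (contig, strand), d in self.states.items():
            codes = ref.encoded(contig)
            want = C if strand == "+" else G
            for pos in d:
                if not (0 <= pos < len(codes)) or codes[pos] != want:
                    raise ValueError(
                        f"modification at ({contig!r}, {pos}, {strand!r}) does not "
                        f"address a {'C' if strand == '+' else 'G'} reference base"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.iter_entries())
        return pd.DataFrame(rows, columns=["contig", "pos0", "strand", "state"])


@dataclass
class ReadSet:
    """Simulated single-end reads plus a truth sidecar.

    ``truth`` has one row per read: read_id, contig, start (0-based, plus
    strand), strand; simulators may append extra truth columns (e.g. the
    per-molecule modification state of a mixture).  Qualities are a constant
    Phred score for every base; the pipeline ignores them.
    """

    names: list[str]
    sequences: list[str]
    truth: pd.DataFrame
    quality_char: str = "I"  # Phred 40

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def to_fastq(self, path_or_handle) -> None:
        """Write 4-line FASTQ records (constant quality string)."""
        if hasattr(path_or_handle, "write"):
            self._write(path_or_handle)
        else:
            with open(path_or_handle, "w") as fh:
                self._write(fh)

    def _write(self, fh) -> None:
        q = self.quality_char
        for name, seq in zip(self.names, self.sequences):
            fh.write(f"@{name}\n{seq}\n+\n{q * len(seq)}\n")

    def fastq_text(self) -> str:
        buf = _io.StringIO()
        self._write(buf)
        return buf.getvalue()
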