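"""Core in-memory containers.

All per-nucleotide tracks are held as float numpy arrays in mRNA 5'->3'
orientation, one value per position, with NaN marking missing values.
Nucleotide coordinates are 0-based half-open; residue coordinates are
1-based inclusive (the Uniprot feature-table convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrnaLookupError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: the 61 sense codons, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass
class TranscriptRecord:
    """One protein-coding gene with its per-nucleotide property tracks.

    ``tracks`` vectors cover the stored mRNA span: ``utr5_len`` UTR values,
    then one value per CDS nucleotide, then ``utr3_len`` UTR values.  After
    UTR trimming both UTR lengths are 0 and every track has exactly
    ``len(cds)`` entries.  ``codon_tracks`` holds per-residue vectors (e.g.
    relative tRNA concentration per codon), one entry per protein residue.
    """

    transcript_id: str
    cds: str
    protein: str
    tracks: dict[str, np.ndarray] = field(default_factory=dict)
    strand: str = "+"
    utr5_len: int = 0
    utr3_len: int = 0
    codon_tracks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mrna_len(self) -> int:
        return self.utr5_len + len(self.cds) + self.utr3_len

    def has_stop(self) -> bool:
        return len(self.cds) == 3 * (len(self.protein) + 1)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty = valid)."""
        problems: list[str] = []
        n_cds, n_res = len(self.cds), len(self.protein)
        if n_cds % 3 != 0:
            problems.append(f"CDS length {n_cds} not a multiple of 3")
        if n_cds not in (3 * n_res, 3 * (n_res + 1)):
            problems.append(
                f"CDS length {n_cds} inconsistent with protein length {n_res}"
            )
        if set(self.cds) - set("ACGT"):
            problems.append("CDS contains non-ACGT symbols")
        if self.strand not in ("+", "-"):
            problems.append(f"invalid strand {self.strand!r}")
        for name, values in self.tracks.items():
            if len(values) != self.mrna_len:
                problems.append(
                    f"track {name!r} has {len(values)} values, expected {self.mrna_len}"
                )
        return problems

    def copy(self) -> "TranscriptRecord":
        return TranscriptRecord(
            transcript_id=self.transcript_id,
            cds=self.cds,
            protein=self.protein,
            tracks={k: v.copy() for k, v in self.tracks.items()},
            strand=self.strand,
            utr5_len=self.utr5_len,
            utr3_len=self.utr3_len,
            codon_tracks={k: v.copy() for k, v in self.codon_tracks.items()},
        )


@dataclass(frozen=True)
class FeatureInstance:
    """One occurrence of a named protein feature (1-based inclusive residues)."""

    protein_id: str
    feature_name: str
    start_res: int
    end_res: int

    def __post_init__(self):
        if not 1 <= self.start_res <= self.end_res:
            raise ValueError(
                f"invalid residue range {self.start_res}..{self.end_res}"
            )

    @property
    def length(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass
class TrnaTable:
    """Relative concentration (fraction of total tRNA) per sense codon."""

    fractions: dict[str, float]

    def __post_init__(self):
        bad = set(self.fractions) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in tRNA table: {sorted(bad)}")
        if any(v <= 0 for v in self.fractions.values()):
            raise ValueError("tRNA fractions must be positive")

    def __getitem__(self, codon: str) -> float:
        codon = codon.upper()
        if codon in STOP_CODONS:
            raise TrnaLookupError(f"stop codon {codon} has no tRNA fraction")
        try:
            return self.fractions[codon]
        except KeyError:
            raise TrnaLookupError(f"codon {codon} absent from tRNA table") from None

    def __contains__(self, codon: str) -> bool:
        return codon in self.fractions

    def __len__(self) -> int:
        return len(self.fractions)

    def total(self) -> float:
        return float(sum(self.fractions.values()))


@dataclass
class Dataset:
    """A transcriptome slice: records, protein feature annotations, tRNA table.

    Transcript and protein identifiers coincide (one contiguous CDS per
    transcript, one protein per transcript).
    """

    transcripts: dict[str, TranscriptRecord]
    features: list[FeatureInstance] = field(default_factory=list)
    trna: TrnaTable | None = None
    ground_truth: dict = field(default_factory=dict)
    load_log: dict = field(default_factory=dict)

    def feature_names(self) -> list[str]:
        return sorted({f.feature_name for f in self.features})

    def instances_of(self, feature_name: str) -> list[FeatureInstance]:
        """Instances of one feature, deterministically ordered."""
        out = [f for f in self.features if f.feature_name == feature_name]
        out.sort(key=lambda f: (f.protein_id, f.start_res, f.end_res))
        return out

    def copy(self) -> "Dataset":
        import copy as _copy

        return Dataset(
            transcripts={k: v.copy() for k, v in self.transcripts.items()},
            features=list(self.features),
            trna=TrnaTable(dict(self.trna.fractions)) if self.trna else None,
            ground_truth=_copy.deepcopy(self.ground_truth),
            load_log=dict(self.load_log),
        )
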