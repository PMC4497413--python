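"""Synthetic transcriptome generator with planted, feature-locked signals.

The generator emulates the data regime of a combined ribosome-profiling /
RNA-structure-probing study on a compact microbial transcriptome:

* CDS-only transcripts (ATG start, sense-codon body, single stop codon);
* a heavy-tailed "occupancy" track (log-normal per-nucleotide read
  density) with a small fraction of multiplicative outlier spikes, the
  kind of artifact an outlier filter must remove;
* a "structure" track whose baseline depends on nucleotide identity
  (pairing propensity differs per base), so that per-base z-scoring is
  consequential;
* a codon->relative-tRNA-concentration table (fractions of total tRNA);
* named protein features placed at random residue ranges, optionally with
  a template profile added to a track, anchored on the first coding
  nucleotide of each instance.

Everything is a pure function of (config, seed): identical inputs give
byte-identical datasets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError
from .types import SENSE_CODONS, STOP_CODONS, Dataset, FeatureInstance, TranscriptRecord, TrnaTable

BASES = "ACGT"

#: default per-base additive offsets of the raw structure score, mimicking
#: the very different score ranges of the four nucleotides (G/C pair more).
DEFAULT_BASE_OFFSETS: dict[str, float] = {"A": -0.6, "C": 1.0, "G": 1.3, "T": -0.9}


@dataclass(frozen=True)
class PlantedTemplate:
    """A profile template over a contiguous relative-nucleotide axis.

    ``values[j]`` applies at relative position ``start + j``; relative
    position 0 is the first nucleotide coding the feature's first residue.
    """

    name: str
    values: np.ndarray
    start: int = -50

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0 or not np.all(np.isfinite(v)):
            raise ValueError("template values must be a finite 1-D vector")
        object.__setattr__(self, "values", v)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.values))


def bump_template(center: int = 12, width: float = 10.0, start: int = -50,
                  stop: int = 100, name: str = "bump") -> PlantedTemplate:
    """Gaussian bump peaking shortly after the feature start.

    Emulates the peak of slow translation covering roughly the first
    ~25 nt of a feature's coding region; unit peak height.
    """
    pos = np.arange(start, stop + 1)
    return PlantedTemplate(name, np.exp(-0.5 * ((pos - center) / width) ** 2), start)


def impulse_template(at: int = 0, start: int = -50, stop: int = 100) -> PlantedTemplate:
    pos = np.arange(start, stop + 1)
    return PlantedTemplate("impulse", (pos == at).astype(float), start)


def ramp_template(start: int = -50, stop: int = 100) -> PlantedTemplate:
    """Monotone decay from the anchor onward (translational-ramp shape)."""
    pos = np.arange(start, stop + 1)
    v = np.where(pos >= 0, np.exp(-pos / 30.0), 0.0)
    return PlantedTemplate("ramp", v, start)


TEMPLATES = {
    "bump": bump_template,
    "impulse": impulse_template,
    "ramp": ramp_template,
}


@dataclass(frozen=True)
class FeatureSpec:
    """How many instances of one named feature to place, and what to plant."""

    name: str
    n_instances: int
    length_range_residues: tuple[int, int] = (5, 30)
    template: str | PlantedTemplate | None = None
    amplitude: float = 0.0
    track: str = "occupancy"

    def resolve_template(self) -> PlantedTemplate | None:
        if self.template is None:
            return None
        if isinstance(self.template, PlantedTemplate):
            return self.template
        return TEMPLATES[self.template]()


@dataclass
class SimConfig:
    n_genes: int = 20
    cds_length_range: tuple[int, int] = (300, 900)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    track_noise_sd: float = 0.5
    occupancy_outlier_rate: float = 0.001
    occupancy_outlier_scale: float = 1000.0
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    base_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_OFFSETS))
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.base_composition, float)
        if p.shape != (4,) or np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        lo, hi = self.cds_length_range
        if lo <= 0 or hi < lo or lo % 3 or hi % 3:
            raise ValueError("cds_length_range must be positive multiples of 3")
        if self.track_noise_sd < 0:
            raise ValueError("track_noise_sd must be >= 0")
        if not 0 <= self.occupancy_outlier_rate <= 1:
            raise ValueError("occupancy_outlier_rate must be a probability")
        if self.occupancy_outlier_scale <= 1:
            raise ValueError("occupancy_outlier_scale must exceed 1")
        for fs in self.feature_specs:
            if fs.n_instances < 0:
                raise ValueError(f"n_instances < 0 for feature {fs.name!r}")
            flo, fhi = fs.length_range_residues
            if flo <= 0 or fhi < flo:
                raise ValueError(f"bad length range for feature {fs.name!r}")


def occupancy_noise_sd(track_noise_sd: float) -> float:
    """Standard deviation of the log-normal occupancy noise.

    Occupancy values are exp(N(0, s)) with s = track_noise_sd, so their
    sd is sqrt((e^{s^2} - 1) e^{s^2}).
    """
    s2 = track_noise_sd**2
    return math.sqrt((math.exp(s2) - 1.0) * math.exp(s2))


def _random_cds(rng: np.random.Generator, n_codons: int, p: np.ndarray) -> str:
    """ATG + (n_codons - 2) sense codons + one stop codon."""
    body: list[str] = []
    while len(body) < n_codons - 2:
        draw = rng.choice(4, size=3, p=p)
        codon = "".join(BASES[i] for i in draw)
        if codon not in STOP_CODONS:
            body.append(codon)
    stop = sorted(STOP_CODONS)[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(body) + stop


def translate_cds(cds: str) -> str:
    """Standard-code translation of a CDS, terminal stop excluded."""
    from Bio.Seq import Seq

    n = len(cds) - len(cds) % 3
    aa = str(Seq(cds[:n]).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def _make_tracks(rng: np.random.Generator, cds: str, cfg: SimConfig) -> dict[str, np.ndarray]:
    n = len(cds)
    occ = np.exp(rng.normal(0.0, cfg.track_noise_sd, size=n))
    spikes = rng.random(n) < cfg.occupancy_outlier_rate
    occ[spikes] *= cfg.occupancy_outlier_scale
    offsets = np.array([cfg.base_offsets[b] for b in cds])
    structure = offsets + rng.normal(0.0, cfg.track_noise_sd, size=n)
    return {"occupancy": occ, "structure": structure}


def _place_instances(rng: np.random.Generator, spec: FeatureSpec,
                     proteins: dict[str, int]) -> list[FeatureInstance]:
    """Uniform random placement, non-overlapping within a feature type."""
    flo, fhi = spec.length_range_residues
    ids = sorted(proteins)
    if spec.n_instances and flo > max(proteins.values(), default=0):
        raise PlacementError(
            f"feature {spec.name!r}: minimum length {flo} exceeds every protein"
        )
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}
    placed: list[FeatureInstance] = []
    attempts_left = 500 * max(spec.n_instances, 1)
    while len(placed) < spec.n_instances:
        if attempts_left <= 0:
            raise PlacementError(
                f"feature {spec.name!r}: could not place "
                f"{spec.n_instances} non-overlapping instances"
            )
        attempts_left -= 1
        pid = ids[rng.integers(len(ids))]
        plen = proteins[pid]
        flen = int(rng.integers(flo, fhi + 1))
        if flen > plen:
            continue
        start = int(rng.integers(1, plen - flen + 2))
        end = start + flen - 1
        if any(s <= end and start <= e for s, e in occupied[pid]):
            continue
        occupied[pid].append((start, end))
        placed.append(FeatureInstance(pid, spec.name, start, end))
    placed.sort(key=lambda f: (f.protein_id, f.start_res))
    return placed


def generate_trna_table(seed: int) -> TrnaTable:
    """Random relative tRNA concentrations for the 61 sense codons.

    Fractions are Dirichlet-distributed, so synonymous codons get
    independent values (codon choice matters) and the fractions sum to 1,
    matching the "fraction of total tRNA" convention of measured
    abundances.
    """
    rng = np.random.default_rng(seed)
    fracs = rng.dirichlet(np.ones(len(SENSE_CODONS)))
    return TrnaTable(dict(zip(SENSE_CODONS, map(float, fracs))))


def generate_dataset(config: SimConfig) -> Dataset:
    """Simulate a full dataset: transcripts, tracks, features, tRNA table.

    Raises :class:`PlacementError` for infeasible feature specs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = np.asarray(config.base_composition, float)
    lo, hi = config.cds_length_range

    transcripts: dict[str, TranscriptRecord] = {}
    n_digits = max(3, len(str(config.n_genes)))
    for i in range(config.n_genes):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = _random_cds(rng, n_codons, p)
        tid = f"g{i:0{n_digits}d}"
        transcripts[tid] = TranscriptRecord(
            transcript_id=tid,
            cds=cds,
            protein=translate_cds(cds),
            tracks=_make_tracks(rng, cds, config),
            strand="+" if rng.random() < 0.5 else "-",
        )

    proteins = {tid: len(r.protein) for tid, r in transcripts.items()}
    features: list[FeatureInstance] = []
    for spec in config.feature_specs:
        features.extend(_place_instances(rng, spec, proteins))

    dataset = Dataset(
        transcripts=transcripts,
        features=features,
        trna=generate_trna_table(int(rng.integers(2**31))),
        ground_truth={"planted": {}},
    )

    for spec in config.feature_specs:
        template = spec.resolve_template()
        if template is not None and spec.amplitude != 0.0:
            plant_signal(dataset, spec.name, template, spec.amplitude, spec.track)
    return dataset


def plant_signal(dataset: Dataset, feature_name: str, template: PlantedTemplate,
                 amplitude: float, track_name: str = "occupancy") -> Dataset:
    """Add ``amplitude * template`` to a track at every instance of a feature.

    The template is anchored so its relative position 0 lands on the first
    nucleotide coding the feature's first residue; template positions
    falling outside the CDS are silently skipped.  Modifies the dataset in
    place and updates its ground-truth record; returns the dataset.
    """
    instances = dataset.instances_of(feature_name)
    if not instances:
        raise KeyError(f"unknown feature name {feature_name!r}")
    if amplitude != 0.0:
        for inst in instances:
            record = dataset.transcripts[inst.protein_id]
            if track_name not in record.tracks:
                raise KeyError(f"unknown track name {track_name!r}")
            track = record.tracks[track_name]
            anchor = record.utr5_len + 3 * (inst.start_res - 1)
            lo_idx = anchor + template.start
            for j, value in enumerate(template.values):
                idx = lo_idx + j
                if record.utr5_len <= idx < record.utr5_len + len(record.cds):
                    track[idx] += amplitude * value
    planted = dataset.ground_truth.setdefault("planted", {})
    planted.setdefault(feature_name, []).append({
        "template": template.name,
        "template_start": int(template.start),
        "template_values": [float(v) for v in template.values],
        "amplitude": float(amplitude),
        "track": track_name,
    })
    return dataset
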