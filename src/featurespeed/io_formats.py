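"""On-disk formats and orientation handling.

A dataset directory holds:

* ``cds.fasta`` / ``proteins.fasta`` — coding sequences and proteins
  (shared identifiers, one contiguous CDS per transcript);
* ``track_<name>.tsv`` — per-nucleotide values, columns
  ``transcript_id, position, value`` with 0-based positions in mRNA
  5'->3' coordinates; dense (one row per CDS position, an empty value
  cell marking a missing measurement) so a row-count mismatch is a
  structural defect;
* ``features.tsv`` — ``protein_id, feature_name, start_res, end_res``
  (1-based inclusive residue ranges, the Uniprot FT convention);
* ``trna.tsv`` — ``codon, fraction`` for the 61 sense codons;
* ``strands.tsv`` (optional) — ``transcript_id, strand``;
* ``ground_truth.json`` (optional) — planted-signal record from the
  simulator.

Loading is tolerant: records or feature rows violating structural
invariants are dropped individually with a logged reason, never failing
the whole load.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import Dataset, FeatureInstance, TranscriptRecord, TrnaTable

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


def orient_track(values, strand: str) -> np.ndarray:
    """Return per-position values in mRNA 5'->3' order.

    '+' leaves the vector unchanged; '-' reverses it (values are scalars
    per position, so no complementation applies).
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand symbol {strand!r}")
    values = np.asarray(values, dtype=float)
    return values.copy() if strand == "+" else values[::-1].copy()


def write_dataset(dataset: Dataset, outdir: str | Path) -> Path:
    """Write a dataset directory readable by :func:`read_dataset`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = sorted(dataset.transcripts)

    SeqIO.write(
        (SeqRecord(Seq(dataset.transcripts[t].cds), id=t, description="") for t in order),
        outdir / "cds.fasta", "fasta",
    )
    SeqIO.write(
        (SeqRecord(Seq(dataset.transcripts[t].protein), id=t, description="") for t in order),
        outdir / "proteins.fasta", "fasta",
    )

    track_names = sorted({n for t in order for n in dataset.transcripts[t].tracks})
    for name in track_names:
        rows = []
        for tid in order:
            values = dataset.transcripts[tid].tracks.get(name)
            if values is None:
                continue
            rows.append(pd.DataFrame({
                "transcript_id": tid,
                "position": np.arange(len(values)),
                "value": values,
            }))
        frame = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=["transcript_id", "position", "value"]))
        frame.to_csv(outdir / f"track_{name}.tsv", sep="\t", index=False,
                     float_format="%.17g")

    pd.DataFrame(
        [(f.protein_id, f.feature_name, f.start_res, f.end_res) for f in dataset.features],
        columns=["protein_id", "feature_name", "start_res", "end_res"],
    ).to_csv(outdir / "features.tsv", sep="\t", index=False)

    if dataset.trna is not None:
        pd.DataFrame(
            sorted(dataset.trna.fractions.items()), columns=["codon", "fraction"]
        ).to_csv(outdir / "trna.tsv", sep="\t", index=False, float_format="%.17g")

    pd.DataFrame(
        [(t, dataset.transcripts[t].strand) for t in order],
        columns=["transcript_id", "strand"],
    ).to_csv(outdir / "strands.tsv", sep="\t", index=False)

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(dataset.ground_truth, fh, indent=1, sort_keys=True)
    return outdir


def read_dataset(indir: str | Path) -> Dataset:
    """Load a dataset directory, dropping invalid records with logged reasons.

    The returned dataset's ``load_log`` counts every exclusion:
    ``no_protein`` (non-mRNA species lacking a protein partner),
    ``bad_track_length``, ``bad_feature_row``.
    """
    indir = Path(indir)
    cds = {r.id: str(r.seq).upper() for r in SeqIO.parse(indir / "cds.fasta", "fasta")}
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(indir / "proteins.fasta", "fasta")}

    strands: dict[str, str] = {}
    if (indir / "strands.tsv").exists():
        sdf = pd.read_csv(indir / "strands.tsv", sep="\t", dtype=str)
        strands = dict(zip(sdf["transcript_id"], sdf["strand"]))

    log = {"no_protein": 0, "bad_track_length": 0, "bad_feature_row": 0}
    records: dict[str, TranscriptRecord] = {}
    for tid, seq in cds.items():
        if tid not in proteins:
            log["no_protein"] += 1
            logger.info("dropping %s: no protein partner (non-mRNA species)", tid)
            continue
        records[tid] = TranscriptRecord(
            transcript_id=tid, cds=seq, protein=proteins[tid],
            strand=strands.get(tid, "+"),
        )

    dropped: set[str] = set()
    for path in sorted(indir.glob("track_*.tsv")):
        name = path.stem[len("track_"):]
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        for tid, group in frame.groupby("transcript_id", sort=True):
            record = records.get(str(tid))
            if record is None:
                continue
            pos = group["position"].to_numpy(dtype=int)
            n = len(record.cds)
            if len(pos) != n or not np.array_equal(np.sort(pos), np.arange(n)):
                log["bad_track_length"] += 1
                dropped.add(str(tid))
                logger.info("dropping %s: track %s has %d rows for a %d-nt CDS",
                            tid, name, len(pos), n)
                continue
            values = np.full(n, np.nan)
            values[pos] = group["value"].to_numpy(dtype=float)
            record.tracks[name] = values

    for tid, record in list(records.items()):
        if tid in dropped:
            del records[tid]
            continue
        problems = record.validate()
        if problems:
            for problem in problems:
                logger.info("dropping %s: %s", tid, problem)
            log["bad_track_length"] += 1
            del records[tid]

    features: list[FeatureInstance] = []
    fpath = indir / "features.tsv"
    if fpath.exists():
        fdf = pd.read_csv(fpath, sep="\t")
        for row in fdf.itertuples(index=False):
            pid = str(row.protein_id)
            record = records.get(pid)
            if (record is None or row.start_res < 1
                    or row.end_res < row.start_res
                    or row.end_res > len(record.protein)):
                log["bad_feature_row"] += 1
                logger.info("rejecting feature row %s %s %s..%s",
                            pid, row.feature_name, row.start_res, row.end_res)
                continue
            features.append(FeatureInstance(pid, str(row.feature_name),
                                            int(row.start_res), int(row.end_res)))

    trna = None
    if (indir / "trna.tsv").exists():
        tdf = pd.read_csv(indir / "trna.tsv", sep="\t", float_precision="round_trip")
        trna = TrnaTable(dict(zip(tdf["codon"].astype(str), tdf["fraction"].astype(float))))

    ground_truth: dict = {}
    if (indir / "ground_truth.json").exists():
        with open(indir / "ground_truth.json") as fh:
            ground_truth = json.load(fh)

    return Dataset(transcripts=records, features=features, trna=trna,
                   ground_truth=ground_truth, load_log=log)


REPORT_COLUMNS = [
    "feature", "track", "n_instances", "n_windows_used",
    "mean_obs_corr", "mean_bg_corr", "t_statistic", "p_value",
]


def report_frame(results) -> pd.DataFrame:
    """Assemble correlation-test results into a report table.

    One row per (feature, track), sorted by feature then track.
    """
    rows = [{
        "feature": r.feature_name,
        "track": r.track_name,
        "n_instances": r.n_instances,
        "n_windows_used": r.n_obs_windows,
        "mean_obs_corr": r.mean_obs,
        "mean_bg_corr": r.mean_bg,
        "t_statistic": r.t_statistic,
        "p_value": r.p_value,
    } for r in results]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return frame.sort_values(["feature", "track"], kind="stable").reset_index(drop=True)


def write_report(results, path: str | Path) -> pd.DataFrame:
    """Write the per-(feature, track) association report as TSV.

    Floats carry 12 significant digits; p-values use scientific notation.
    """
    frame = report_frame(results)
    out = frame.copy()
    for col in ("mean_obs_corr", "mean_bg_corr", "t_statistic"):
        out[col] = out[col].map(lambda v: _FLOAT_FMT % v)
    out["p_value"] = out["p_value"].map(lambda v: "%.12e" % v)
    out.to_csv(path, sep="\t", index=False)
    return frame
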