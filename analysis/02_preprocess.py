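"""Condition the tracks: outlier exclusion, per-base z-scoring, screens.

Loads results/data/, removes occupancy values more than 1.5 pooled sd
above the pooled mean (the spikes the generator plants as artifacts),
z-scores the structure track per nucleotide identity, applies the 5%
translation-discrepancy screen, and reports every exclusion count.
"""
import json

from common import RESULTS, load_prepared


def main() -> None:
    dataset, log, _ = load_prepared()
    print(f"retained transcripts: {len(dataset.transcripts)}")
    print(f"translation-discrepancy exclusions: {log['discrepancy_dropped']}")
    print(f"occupancy outliers removed: {log['outliers_removed_occupancy']}")
    print("per-base statistics of the raw structure score:")
    for base, st in sorted(log["base_stats_structure"].items()):
        print(f"  {base}: mean {st['mu']:+.3f}  sd {st['sigma']:.3f}  "
              f"n {st['n']}")
    out = RESULTS / "preprocess_log.json"
    with open(out, "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    print(f"log -> {out}")


if __name__ == "__main__":
    main()
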