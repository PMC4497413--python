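"""Generate the study's synthetic transcriptome and write it to disk.

Produces results/data/: CDS and protein FASTA, per-nucleotide track
TSVs, feature annotations, tRNA fractions, and the ground-truth record
of what was planted where.
"""
import sys

import featurespeed as fs
from common import DATA_DIR, DEFAULT_SEED, build_demo_dataset


def main(seed: int = DEFAULT_SEED) -> None:
    dataset = build_demo_dataset(seed)
    fs.write_dataset(dataset, DATA_DIR)
    n_nt = sum(len(r.cds) for r in dataset.transcripts.values())
    print(f"wrote {len(dataset.transcripts)} transcripts ({n_nt} coding nt) "
          f"to {DATA_DIR}")
    for name in dataset.feature_names():
        planted = dataset.ground_truth["planted"].get(name, [])
        tracks = ", ".join(p["track"] for p in planted) or "none"
        print(f"  {name}: {len(dataset.instances_of(name))} instances, "
              f"planted signal: {tracks}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
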