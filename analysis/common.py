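"""Shared study design for the analysis scripts.

One synthetic transcriptome, four annotated protein features:

* ``dual_bump`` — a peak template planted on BOTH tracks, displaced by
  10 nt (occupancy peak at +12, structure peak at +22), emulating a
  feature whose two translation-speed proxies correlate with a shift;
* ``occ_only`` — a peak planted on ribosome occupancy alone;
* ``null_a`` / ``null_b`` — randomly placed features with no signal.
"""
from pathlib import Path

import featurespeed as fs

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"
DEFAULT_SEED = 7

OCC_AMPLITUDE = 2.0 * fs.occupancy_noise_sd(0.5)
STRUCT_AMPLITUDE = 1.0  # raw structure units; ~2 z-units after normalization


def demo_config(seed: int = DEFAULT_SEED) -> fs.SimConfig:
    return fs.SimConfig(
        n_genes=40,
        cds_length_range=(450, 750),
        track_noise_sd=0.5,
        feature_specs=[
            fs.FeatureSpec("dual_bump", 60, (5, 15)),
            fs.FeatureSpec("occ_only", 60, (5, 15), template="bump",
                           amplitude=OCC_AMPLITUDE),
            fs.FeatureSpec("null_a", 40, (5, 15)),
            fs.FeatureSpec("null_b", 40, (5, 15)),
        ],
        seed=seed,
    )


def build_demo_dataset(seed: int = DEFAULT_SEED) -> fs.Dataset:
    dataset = fs.generate_dataset(demo_config(seed))
    fs.plant_signal(dataset, "dual_bump",
                    fs.bump_template(center=12), OCC_AMPLITUDE, "occupancy")
    fs.plant_signal(dataset, "dual_bump",
                    fs.bump_template(center=22), STRUCT_AMPLITUDE, "structure")
    return dataset


def load_prepared(seed: int = DEFAULT_SEED):
    """Read the dataset written by 01_simulate.py and condition its tracks."""
    config = fs.RunConfig(input_dir=DATA_DIR, seed=seed)
    from featurespeed.pipeline import prepare_dataset

    return prepare_dataset(config) + (config,)
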