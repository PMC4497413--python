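import numpy as np
import pytest

import featurespeed as fs


@pytest.fixture
def record_factory():
    """Build a TranscriptRecord from a CDS and per-nucleotide tracks.

    The protein is derived by translation, so records are always
    internally consistent unless a test overrides ``protein``.
    """

    def make(cds: str, tracks: dict | None = None, protein: str | None = None,
             transcript_id: str = "t1", **kwargs) -> fs.TranscriptRecord:
        tracks = {k: np.asarray(v, dtype=float) for k, v in (tracks or {}).items()}
        return fs.TranscriptRecord(
            transcript_id=transcript_id,
            cds=cds,
            protein=protein if protein is not None else fs.simulate.translate_cds(cds),
            tracks=tracks,
            **kwargs,
        )

    return make


@pytest.fixture
def small_config():
    return fs.SimConfig(
        n_genes=6,
        cds_length_range=(300, 450),
        feature_specs=[fs.FeatureSpec("f1", 10, (3, 8))],
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    return fs.generate_dataset(small_config)
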