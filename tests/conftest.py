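import numpy as np
import pytest

from gpsuc import profiles, seqio, synthetic
from gpsuc.alphabet import CANONICAL, WINDOW


@pytest.fixture
def record():
    return seqio.ProteinRecord("P1", "MKAAKAAAAKLLLKEEDDRRKSTVWYHICG" * 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_window(rng):
    """A random interior window with a K centre and no padding."""
    symbols = "".join(rng.choice(list(CANONICAL), size=WINDOW))
    symbols = symbols[:20] + "K" + symbols[21:]
    return seqio.SequenceWindow(symbols, "R1", 100)


@pytest.fixture
def random_profile_window(rng):
    rows = rng.normal(scale=3.0, size=(WINDOW, 20))
    return profiles.ProfileWindow(rows, "R1", 100)


@pytest.fixture(scope="session")
def small_dataset():
    """A small motif-enriched synthetic dataset shared across tests."""
    spec = synthetic.SyntheticSpec(
        n_proteins=25, length_range=(60, 110), effect_size=1.0, seed=7
    )
    return synthetic.generate(spec)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """A labelled 1:2 feature matrix built from the small dataset."""
    from gpsuc.encoders import build_feature_matrix
    from gpsuc.profiles import profile_window

    records, sites, profs = small_dataset
    windows = seqio.windows_for_sites(records, sites)
    pos = [w for w in windows if w.label == "positive"]
    neg = [w for w in windows if w.label != "positive"]
    train = seqio.sample_training_set(pos, neg, seed=7)
    pwins = [profile_window(profs[w.protein_id], w.site_position) for w in train]
    return build_feature_matrix(train, pwins)
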