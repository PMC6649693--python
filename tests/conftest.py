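import numpy as np
import pytest

from titramap import PeakList, ResidueAssignment, SimConfig, generate_titration


def make_peaklist(label, ratio, rows):
    """rows: (index, code, h, n, intensity) tuples; None values stay missing."""
    return PeakList(
        label=label,
        molar_ratio=ratio,
        entries=[
            ResidueAssignment(
                residue_index=i, residue_code=c, shift_h=h, shift_n=n, intensity=inten
            )
            for i, c, h, n, inten in rows
        ],
    )


@pytest.fixture
def free_bound_pair():
    free = make_peaklist(
        "free",
        0.0,
        [
            (10, "A", 8.20, 123.0, 1.0e6),
            (11, "K", 8.30, 121.0, 1.2e6),
            (12, "G", 8.33, 109.5, 0.9e6),
        ],
    )
    bound = make_peaklist(
        "bound",
        2.0,
        [
            (10, "A", 8.30, 123.5, 5.0e5),
            (11, "K", 8.30, 121.0, 1.2e6),
            (12, "G", 8.35, 110.0, 1.8e5),
        ],
    )
    return free, bound


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic titration shared by read-only tests."""
    return generate_titration(SimConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate_titration(
        SimConfig(seed=7, noise_shift_sd=0.0, noise_intensity_cv=0.0)
    )
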