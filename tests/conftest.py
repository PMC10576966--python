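import numpy as np
import pytest

from topoptm import FixtureSpec, PointCloud, synth_structure

SQ3 = np.sqrt(3.0)


@pytest.fixture(scope="session")
def unit_square() -> PointCloud:
    return PointCloud(
        np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float),
        ("C", "C", "C", "C"),
    )


@pytest.fixture(scope="session")
def equilateral_triangle() -> PointCloud:
    return PointCloud(
        np.array([[0, 0, 0], [1, 0, 0], [0.5, SQ3 / 2, 0]], dtype=float),
        ("C", "C", "C"),
    )


@pytest.fixture(scope="session")
def demo_sequence() -> str:
    # all 20 residue types, lysine at the center (position 21)
    return "ACDEFGHIWLMNPQRSTVWY" + "K" + "ACDEFGHIYLMNPQRSTVWM"


@pytest.fixture(scope="session")
def compact_structure(demo_sequence):
    return synth_structure(FixtureSpec(demo_sequence, "compact", 0.0, 0))


@pytest.fixture(scope="session")
def extended_structure(demo_sequence):
    return synth_structure(FixtureSpec(demo_sequence, "extended", 0.0, 0))


def random_cloud(seed: int, n_min: int = 2, n_max: int = 8) -> PointCloud:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    return PointCloud(rng.uniform(0.0, 3.0, (n, 3)), ("C",) * n)


def canonical_bars(barcode, dims=(0, 1, 2), ndigits=9):
    """Barcode as a comparable dict: sorted rounded finite pairs plus the
    infinite-bar count, per dimension."""
    return {
        d: (
            sorted(
                (round(b.birth, ndigits), round(b.death, ndigits))
                for b in barcode.finite_bars(d)
            ),
            barcode.n_infinite(d),
        )
        for d in dims
    }
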