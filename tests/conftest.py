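import numpy as np
import pytest

from gyrimetry.geometry import Polyline


def rigid(vertices: np.ndarray, angle: float, tx: float = 0.0, ty: float = 0.0,
          scale: float = 1.0) -> np.ndarray:
    """Apply rotation + translation (+ optional uniform scaling) to (n,2) vertices."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return scale * vertices @ rot.T + np.array([tx, ty])


def semicircle(n: int = 1000, radius: float = 1.0, closed: bool = False) -> Polyline:
    """Upper semicircular arc sampled from (+r, 0) to (−r, 0)."""
    theta = np.linspace(0.0, np.pi, n)
    verts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return Polyline(verts, closed=closed)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def phantom():
    """One mirror-symmetric default phantom section (cells + image included)."""
    from gyrimetry.synthetic import PhantomSpec, generate_section

    return generate_section(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def null_animal_means():
    """(control, treated) animal-mean GS ratios for 200 null cohort replicates.

    Both groups share the same symmetric phantom spec, so any detected
    difference is a false positive; used to calibrate the t-tests.
    """
    from gyrimetry.synthetic import PhantomSpec, cohort_ratios, generate_cohort

    spec = PhantomSpec()
    out = []
    for rep in range(200):
        cohort = generate_cohort(spec, spec, seed=1000 + rep, compute_truth=False)
        df = cohort_ratios(cohort)
        sub = df[df["metric"] == "local_gs"].drop_duplicates(["group", "animal_id"])
        c = sub.loc[sub["group"] == "control", "animal_mean"].to_numpy()
        t = sub.loc[sub["group"] == "treated", "animal_mean"].to_numpy()
        out.append((c, t))
    return out
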