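import numpy as np
import pytest

from elmcortex import CohortSpec, FeatureTable, generate_cohort, normalize_minmax
from elmcortex.schema import REGIONS, generic_descriptors

STATS_COLUMNS = ("StructName", "NumVert", "SurfArea", "GrayVol", "ThickAvg",
                 "ThickStd", "MeanCurv", "GausCurv", "FoldInd", "CurvInd")


def stats_value(region_pos: int, hemi: str, column: str) -> float:
    """Deterministic, distinct value for every (region, hemi, column) cell."""
    h = 0 if hemi == "lh" else 1
    c = STATS_COLUMNS.index(column)
    return round(1000 * h + 10 * region_pos + c / 10.0, 1)


def write_stats_file(path, hemi: str, skip_regions=()):
    """Emit a FreeSurfer-style parcellation summary table (synthetic)."""
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        f"# hemi {hemi}",
        "# ColHeaders " + " ".join(STATS_COLUMNS),
    ]
    for pos, region in enumerate(REGIONS):
        if region in skip_regions:
            continue
        row = [region] + [
            f"{stats_value(pos, hemi, col):.1f}" for col in STATS_COLUMNS[1:]]
        lines.append("  ".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def stats_pair(tmp_path):
    lh = write_stats_file(tmp_path / "lh.aparc.stats", "lh")
    rh = write_stats_file(tmp_path / "rh.aparc.stats", "rh")
    return lh, rh


def random_table(rng, n=12, d=6, normalized=False) -> FeatureTable:
    labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    values = rng.normal(size=(n, d))
    t = FeatureTable(values, labels, [f"S{i}" for i in range(n)],
                     generic_descriptors([f"f{j}" for j in range(d)]))
    return normalize_minmax(t) if normalized else t


@pytest.fixture
def small_table():
    return random_table(np.random.default_rng(42))


@pytest.fixture
def separable_cohort():
    """Strongly separable synthetic cohort, normalized."""
    spec = CohortSpec(effect_size=2.0, seed=7)
    return spec, normalize_minmax(generate_cohort(spec))
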