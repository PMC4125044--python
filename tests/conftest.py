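"""Shared fixtures: a default virtual scope and analysis helpers."""
from __future__ import annotations

import numpy as np
import pytest

from divplane import geometry, localize
from divplane.synthgen import ScopeConfig


@pytest.fixture(scope="session")
def scope() -> ScopeConfig:
    return ScopeConfig()


def analyze_single_cell(img, flag_pairs: bool = False):
    """Segment, axis-extract, and profile the single cell in ``img``."""
    records = geometry.segment_cells(img, flag_division_pairs=flag_pairs)
    assert len(records) == 1, f"expected 1 cell, segmented {len(records)}"
    rec = records[0]
    if rec.axis_px is None:
        geometry.extract_axis(rec, image=img)
    profiles = geometry.line_profiles(img, rec)
    return rec, profiles


def localize_single_cell(img, **kw):
    rec, profiles = analyze_single_cell(img)
    return localize.localize_cell(profiles, **kw), rec


def voxelized_volume_fraction(truth, voxel: float = 0.02) -> float:
    """Independent 3-D voxel integration of the generative division pair.

    Counts voxels of the solid of revolution on each side of the waist;
    serves as the oracle for the 2-D geometric volume estimator.
    """
    s = np.arange(voxel / 2, truth.length, voxel)
    h = truth.half_width(s)
    y = np.arange(-truth.radius - voxel, truth.radius + voxel, voxel)
    yy, zz = np.meshgrid(y, y)
    r2 = yy**2 + zz**2
    counts = np.array([(r2 <= hh**2).sum() for hh in h])
    s_c = truth.constriction_position()
    return float(counts[s < s_c].sum() / counts.sum())
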