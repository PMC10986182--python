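"""Local LGE features around initiation sites and activation-time summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DimensionError
from .mesh import LGEMap, TissueMesh
from .records import ActivationRecord


@dataclass
class SiteFeatures:
    """LGE features inside a Euclidean ball around an initiation site."""

    mean_lge_pct: float
    max_lge_pct: float
    lge_volume_ml: float
    radius_mm: float
    n_elements: int


def local_lge_features(center_mm, mesh: TissueMesh, lge: LGEMap,
                       radius_mm: float = 5.0,
                       lge_threshold: float = 0.0) -> SiteFeatures:
    """Mean/max LGE intensity (%) and LGE volume (mL) within ``radius_mm``.

    The ball is Euclidean around the site; LGE volume sums the volume of
    selected elements with intensity above ``lge_threshold``.
    """
    lge.check_mesh(mesh)
    center = np.asarray(center_mm, dtype=float)
    if center.size == 2:
        center = np.append(center, mesh.extent_mm[2] / 2.0)
    d = np.linalg.norm(mesh.centers - center, axis=1)
    sel = d <= radius_mm
    if not sel.any():
        raise DimensionError("empty feature ball: site off-mesh?")
    vals = lge.intensity[sel]
    vol = float((vals > lge_threshold).sum()) * mesh.element_volume_ml
    return SiteFeatures(mean_lge_pct=float(vals.mean() * 100.0),
                        max_lge_pct=float(vals.max() * 100.0),
                        lge_volume_ml=vol, radius_mm=float(radius_mm),
                        n_elements=int(sel.sum()))


@dataclass
class ActivationSummary:
    fraction: float
    time_ms: float
    reached: bool


def activation_summary(record: ActivationRecord,
                       fractions=(0.95, 1.0)) -> list:
    """Earliest time at which each given fraction of the conducting
    vertices has activated at least once; unreached fractions are flagged
    (cleft models may never activate every vertex)."""
    first = record.first_times()[record.active_mask]
    n = first.size
    if n == 0:
        raise ConfigError("record has no conducting vertices")
    act = np.sort(first[np.isfinite(first)])
    out = []
    for f in fractions:
        need = int(np.ceil(f * n))
        if need == 0:
            out.append(ActivationSummary(f, 0.0, True))
        elif act.size >= need:
            out.append(ActivationSummary(f, float(act[need - 1]), True))
        else:
            out.append(ActivationSummary(f, np.nan, False))
    return out
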