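"""Assembling full electrophysiological models from a mesh + LGE map.

The six model variants:

========== ===================== ========================== ===========
variant    fibrosis structure    conductivity               remodeling
========== ===================== ========================== ===========
cleft_gm   clefts (fib_max 0-9)  step-wise band reduction   yes
cleft_m    clefts (fib_max 0-9)  normal                     yes
cleft_g    none (fib_max 0)      step-wise band reduction   no*
cleft_only clefts (fib_max 0-9)  normal                     no
noncleft_c core + border zone    BZ reduced, core 0.01 S/m  yes
noncleft_nc core + border zone   BZ reduced, core 1e-7 S/m  yes
========== ===================== ========================== ===========

(*) cleft_g ships without ionic remodeling (an illustrative control with
conductivity reduction only); ``cleft_g_remodeling=True`` restores the
alternative reading of the study design.
"""

from __future__ import annotations

import numpy as np

from .cell import CellParams, apply_hcm_remodeling
from .errors import ConfigError
from .mesh import LGEMap, TissueMesh
from .monodomain import MonodomainModel, SimulationConfig
from .tissue import (DEFAULT_SIGMA_SM, assign_cleft_conductivity,
                     assign_noncleft_regions, build_fibmax_ladder,
                     default_fibmax_ladder, remodeling_mask)

CLEFT_VARIANTS = ("cleft_gm", "cleft_m", "cleft_g", "cleft_only")
NONCLEFT_VARIANTS = ("noncleft_c", "noncleft_nc")
ALL_VARIANTS = CLEFT_VARIANTS + NONCLEFT_VARIANTS

#: parameter levels per variant in the full study design
DEFAULT_LEVELS = {
    "cleft_gm": tuple(range(10)),
    "cleft_m": tuple(range(10)),
    "cleft_g": (0,),
    "cleft_only": tuple(range(10)),
    "noncleft_c": (25, 50, 75),
    "noncleft_nc": (25, 50, 75),
}


def build_model(mesh: TissueMesh, lge: LGEMap, variant: str, level,
                seed: int = 0, config: SimulationConfig | None = None,
                sigma_table: dict | None = None,
                cleft_alpha: float = 2.0,
                cleft_g_remodeling: bool = False,
                ladder=None) -> MonodomainModel:
    """Build the monodomain model for one variant at one parameter level."""
    if variant not in ALL_VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    tab = sigma_table or DEFAULT_SIGMA_SM
    healthy = CellParams()
    fibrotic = apply_hcm_remodeling(healthy)
    n = mesh.n_elements

    if variant in CLEFT_VARIANTS:
        level = int(level)
        if variant == "cleft_g" and level != 0:
            raise ConfigError("cleft_g only exists at fib_max 0")
        if not 0 <= level <= 9:
            raise ConfigError(f"fib_max must be 0-9, got {level}")
        if variant == "cleft_g" or level == 0:
            severed, removed = None, None
        else:
            if ladder is None:
                ladder = build_fibmax_ladder(
                    mesh, lge, default_fibmax_ladder(cleft_alpha, seed))
            cm = ladder[level]
            severed, removed = cm.severed, cm.removed_elements
        if variant in ("cleft_gm", "cleft_g"):
            regions = assign_cleft_conductivity(lge, tab)
            sl, st = regions.sigma_l, regions.sigma_t
        else:  # cleft_m, cleft_only: normal conductivity everywhere
            sl = np.full(n, tab["healthy_l"])
            st = np.full(n, tab["healthy_t"])
        if variant in ("cleft_gm", "cleft_m"):
            mask = remodeling_mask(lge)
        elif variant == "cleft_g":
            mask = remodeling_mask(lge) if cleft_g_remodeling \
                else np.zeros(n, dtype=bool)
        else:
            mask = np.zeros(n, dtype=bool)
        return MonodomainModel(mesh, sl, st, remodeled_mask=mask,
                               healthy=healthy, fibrotic=fibrotic,
                               severed_faces=severed,
                               removed_elements=removed, config=config)

    # non-cleft variants
    regions = assign_noncleft_regions(lge, int(level),
                                      variant.split("_")[1], tab)
    mask = remodeling_mask(lge)
    return MonodomainModel(mesh, regions.sigma_l, regions.sigma_t,
                           remodeled_mask=mask, healthy=healthy,
                           fibrotic=fibrotic, config=config)
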