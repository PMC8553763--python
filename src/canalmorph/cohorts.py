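"""Reference validation cohorts.

The package is validated against the published morphology of a 101-tooth
mandibular-canine sample: 98 single-rooted and 3 two-rooted teeth with a
known root-canal-configuration (RCC) frequency composition, known
physiological-foramen count/shape distributions, known accessory- and
connecting-canal locations, and known apical metrology statistics per
foramen-count stratum.  Because the underlying scans are not public, the
composition is realised as synthetic phantoms: the discrete structure
(codes, counts, thirds, shapes) is fixed by the composition, continuous
nuisance geometry is jittered per phantom.

Two cohorts are provided:

* :func:`study_composition` - the full 101-tooth cohort (frequency tables);
* :func:`metrology_specs` - 79 one-foramen phantoms whose constriction axes
  (W, N) and constriction-to-opening distances (D) are drawn from truncated
  normal distributions matching the reference one-foramen statistics
  (means 0.40/0.28/0.45 mm, SD 0.11/0.07/0.17, truncated to the observed
  min/max).  W and N are coupled comonotonically (a large foramen is large
  in both axes), which also keeps every sampled foramen oval, matching the
  reference shape table.

Phantoms use a desk-scale geometry (6.6 mm roots, 1.8 mm crowns at 0.02 mm
voxels); every measured quantity is scale-free or set directly by the
composition, so this affects runtime only.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .phantom import (
    AccessorySpec,
    ConnectingSpec,
    ForamenSpec,
    PhantomSpec,
    RootSpec,
)

__all__ = [
    "GEOMETRY",
    "REFERENCE_RCC_SINGLE",
    "REFERENCE_METROLOGY",
    "study_composition",
    "metrology_specs",
]

#: desk-scale phantom geometry shared by the validation cohorts
GEOMETRY = dict(
    crown_height_mm=1.8,
    root_radius_mm=1.05,
    crown_radius_mm=1.25,
    voxel_size_mm=0.02,
    noise_sd=8.0,
)
ROOT_LENGTH_MM = 6.6
TWO_ROOT_LENGTHS_MM = (6.6, 6.3)

#: single-rooted RCC composition (code -> number of teeth; 98 total)
REFERENCE_RCC_SINGLE = {
    "1-1-1/1": 73,
    "1-1-1/2": 14,
    "1-1-1/3": 1,
    "1-1-1/4": 2,
    "1-1-2/1": 1,
    "1-2-1/1": 4,
    "1-2-1/2": 1,
    "1-2-2/2": 1,
    "2-3-1/1": 1,
}

#: per-stratum (foramen count) metrology: W/N/D (mean, sd, min, max) in mm
REFERENCE_METROLOGY = {
    1: {"W": (0.40, 0.11, 0.21, 0.88), "N": (0.28, 0.07, 0.14, 0.63),
        "D": (0.45, 0.17, 0.10, 0.94)},
    2: {"W": (0.38, 0.11, 0.22, 0.74), "N": (0.22, 0.07, 0.12, 0.40),
        "D": (0.16, 0.05, 0.10, 0.29)},
    3: {"W": (0.32, 0.06, 0.25, 0.38), "N": (0.17, 0.02, 0.15, 0.21),
        "D": (0.17, 0.02, 0.14, 0.19)},
    4: {"W": (0.32, 0.09, 0.23, 0.49), "N": (0.18, 0.03, 0.13, 0.24),
        "D": (0.18, 0.04, 0.13, 0.24)},
}

#: one-foramen shape composition among the 79 one-foramen single-rooted teeth
SHAPES_ONE_FORAMEN = {"oval": 72, "round": 6, "irregular": 1}

#: accessory canal locations among single-rooted teeth (one canal each)
ACCESSORY_SINGLE = {"middle": 7, "apical": 6}


def _foramen(stratum: int, shape: str = "oval") -> ForamenSpec:
    mw, _, _, _ = REFERENCE_METROLOGY[stratum]["W"]
    mn = REFERENCE_METROLOGY[stratum]["N"][0]
    md = REFERENCE_METROLOGY[stratum]["D"][0]
    if shape == "round":
        mn = mw - 0.005          # well below the 0.02 mm oval threshold
    return ForamenSpec(wide_mm=mw, narrow_mm=mn, offset_mm=md, shape=shape)


def _single(code: str, shape: str = "oval",
            accessories: tuple[AccessorySpec, ...] = (),
            connectors: tuple[ConnectingSpec, ...] = ()) -> PhantomSpec:
    f = int(code.split("/")[1])
    foramina = tuple(_foramen(f, shape if f == 1 else "oval") for _ in range(f))
    return PhantomSpec(
        roots=(RootSpec(code, ROOT_LENGTH_MM, foramina, accessories, connectors),),
        **GEOMETRY,
    )


def study_composition() -> list[tuple[PhantomSpec, int]]:
    """The full 101-tooth validation cohort as (spec, count) rows.

    Single-rooted teeth follow :data:`REFERENCE_RCC_SINGLE`; shapes among
    one-foramen teeth, accessory canal locations and the two connecting
    canals (one loop-type on a 1-2-1/1, one communicating on the 2-3-1/1)
    follow the reference composition.  Two-rooted teeth (3): buccal/lingual
    code pairs 1-1-1/1+1-1-1/1, 1-1-1/1+1-1-1/2 and 1-2-1/1+1-1-1/1, one of
    which carries a middle-third accessory canal on the buccal root.
    """
    comp: list[tuple[PhantomSpec, int]] = []
    # modal one-foramen teeth carry the shape and accessory sub-compositions
    n_modal = REFERENCE_RCC_SINGLE["1-1-1/1"]           # 73
    n_round = SHAPES_ONE_FORAMEN["round"]
    n_irregular = SHAPES_ONE_FORAMEN["irregular"]
    n_acc_mid = ACCESSORY_SINGLE["middle"]
    n_acc_api = ACCESSORY_SINGLE["apical"]
    plain = n_modal - n_round - n_irregular - n_acc_mid - n_acc_api
    comp.append((_single("1-1-1/1"), plain))
    comp.append((_single("1-1-1/1", shape="round"), n_round))
    comp.append((_single("1-1-1/1", shape="irregular"), n_irregular))
    comp.append((_single("1-1-1/1", accessories=(AccessorySpec("middle", 0.10),)),
                 n_acc_mid))
    comp.append((_single("1-1-1/1", accessories=(AccessorySpec("apical", 0.10),)),
                 n_acc_api))
    for code, n in REFERENCE_RCC_SINGLE.items():
        if code == "1-1-1/1":
            continue
        if code == "1-2-1/1":
            comp.append((_single(code, connectors=(ConnectingSpec("middle", "L"),)), 1))
            comp.append((_single(code), n - 1))
        elif code == "2-3-1/1":
            comp.append((_single(code, connectors=(ConnectingSpec("middle", "C"),)), n))
        else:
            comp.append((_single(code), n))

    def _two(rcc_b: str, rcc_l: str, acc_b=()) -> PhantomSpec:
        fb = tuple(_foramen(int(rcc_b.split("/")[1])) for _ in range(int(rcc_b.split("/")[1])))
        fl = tuple(_foramen(int(rcc_l.split("/")[1])) for _ in range(int(rcc_l.split("/")[1])))
        return PhantomSpec.two_rooted(
            rcc_b, rcc_l, lengths_mm=TWO_ROOT_LENGTHS_MM,
            foramina_buccal=fb, foramina_lingual=fl,
            accessories_buccal=acc_b, **GEOMETRY,
        )

    comp.append((_two("1-1-1/1", "1-1-1/1", acc_b=(AccessorySpec("middle", 0.10),)), 1))
    comp.append((_two("1-1-1/1", "1-1-1/2"), 1))
    comp.append((_two("1-2-1/1", "1-1-1/1"), 1))
    assert sum(n for _, n in comp) == 101
    return comp


def _trunc(rng: np.random.Generator, mean, sd, lo, hi, u=None) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if u is None:
        u = rng.uniform()
    return float(truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def metrology_specs(seed: int, n: int = 79) -> list[PhantomSpec]:
    """``n`` one-foramen phantoms with sampled constriction geometry.

    W and N share the sampling quantile (comonotone coupling), which keeps
    N < W for every draw and reproduces both marginal distributions; D is
    drawn independently.  Each spec gets its own sub-seed for the volume
    noise.
    """
    stats = REFERENCE_METROLOGY[1]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    specs = []
    for i in range(n):
        u = rng.uniform()
        w = _trunc(rng, *stats["W"], u=u)
        nn = _trunc(rng, *stats["N"], u=u)
        d = _trunc(rng, *stats["D"])
        fo = ForamenSpec(wide_mm=round(w, 4), narrow_mm=round(nn, 4),
                         offset_mm=round(d, 4), shape="oval",
                         angle_deg=float(rng.uniform(0.0, 180.0)))
        specs.append(PhantomSpec(
            roots=(RootSpec("1-1-1/1", ROOT_LENGTH_MM, (fo,)),),
            seed=int(rng.integers(0, 2**31 - 1)),
            **GEOMETRY,
        ))
    return specs
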