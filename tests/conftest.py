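"""Shared fixtures: desk-scale phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from canalmorph import (
    PhantomSpec,
    PipelineConfig,
    analyze_volume,
    make_tooth_phantom,
    render_label_volume,
)
from canalmorph.phantom import AccessorySpec, ConnectingSpec, ForamenSpec, RootSpec

#: small but fully resolvable phantom geometry (0.02 mm voxels)
GEOM = dict(
    crown_height_mm=1.8,
    root_radius_mm=1.05,
    crown_radius_mm=1.25,
    voxel_size_mm=0.02,
    noise_sd=8.0,
)
ROOT_LEN = 6.6


def single_spec(rcc="1-1-1/1", seed=7, noise_sd=GEOM["noise_sd"], foramina=None,
                accessories=(), connectors=()) -> PhantomSpec:
    geom = {**GEOM, "noise_sd": noise_sd}
    return PhantomSpec(
        roots=(RootSpec(rcc, ROOT_LEN, foramina, accessories, connectors),),
        seed=seed, **geom,
    )


@pytest.fixture(scope="session")
def phantom_111():
    """Modal single-canal phantom (with noise) and its ground truth."""
    return make_tooth_phantom(single_spec())


@pytest.fixture(scope="session")
def phantom_121():
    """Split-and-merge (1-2-1/1) phantom and its ground truth."""
    return make_tooth_phantom(single_spec("1-2-1/1", seed=21))


@pytest.fixture(scope="session")
def labels_111():
    """Noise-free generator label volume for the modal phantom."""
    return render_label_volume(single_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def report_111(phantom_111):
    vol, _ = phantom_111
    return analyze_volume(vol, PipelineConfig(), tooth_id="fixture-111")


def battery_cases():
    """All nine single-rooted codes plus both two-rooted variants."""
    multi = ForamenSpec(0.38, 0.22, 0.16)

    def foramina(code):
        f = int(code.split("/")[1])
        return None if f == 1 else tuple(multi for _ in range(f))

    cases = []
    for i, code in enumerate([
        "1-1-1/1", "1-1-1/2", "1-1-1/3", "1-1-1/4", "1-1-2/1",
        "1-2-1/1", "1-2-1/2", "1-2-2/2", "2-3-1/1",
    ]):
        connectors = ()
        if code == "1-2-1/1":
            connectors = (ConnectingSpec("middle", "L"),)
        if code == "2-3-1/1":
            connectors = (ConnectingSpec("middle", "C"),)
        cases.append(single_spec(code, seed=100 + i, foramina=foramina(code),
                                 connectors=connectors))
    cases.append(PhantomSpec.two_rooted(
        "1-1-1/1", "1-1-1/2", lengths_mm=(ROOT_LEN, ROOT_LEN - 0.3),
        foramina_lingual=(multi, multi), seed=300, **GEOM,
    ))
    cases.append(PhantomSpec.two_rooted(
        "1-2-1/1", "1-1-1/1", lengths_mm=(ROOT_LEN, ROOT_LEN - 0.3),
        seed=301, **GEOM,
    ))
    return cases


@pytest.fixture(scope="session")
def battery_results():
    """Pipeline results for the full code battery (computed once)."""
    out = []
    for spec in battery_cases():
        vol, gt = make_tooth_phantom(spec)
        report = analyze_volume(vol, PipelineConfig(), tooth_id="battery")
        out.append((spec, gt, report))
    return out
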