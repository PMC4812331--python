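from __future__ import annotations

import numpy as np
import pytest

from mznet import (
    ClusterParams,
    FilterParams,
    Peak,
    SimilarityParams,
    Spectrum,
    SyntheticDesign,
    attribute_groups,
    build_network,
    cluster_spectra,
    flag_media_nodes,
    generate_cohort,
    preprocess_spectrum,
)


def make_spectrum(
    mzs, intensities=None, precursor=1000.0, spectrum_id="s1", sample_id="sampleA"
) -> Spectrum:
    if intensities is None:
        intensities = [1.0] * len(mzs)
    return Spectrum(
        spectrum_id=spectrum_id,
        sample_id=sample_id,
        precursor_mz=precursor,
        peaks=tuple(Peak(float(m), float(i)) for m, i in zip(mzs, intensities)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


#: small two-location cohort used by clustering / stats / pipeline tests
SMALL_DESIGN = SyntheticDesign(
    groups={"Antarctica": 2, "Scotland": 2},
    n_shared_compounds=4,
    n_group_exclusive=5,
    n_strain_exclusive=2,
    n_media_compounds=2,
    replicates=2,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_DESIGN)


@pytest.fixture(scope="session")
def small_run(small_cohort):
    """Cohort pushed through filter -> cluster -> network -> attribution."""
    fp = FilterParams()
    sp = SimilarityParams()
    filtered = [
        s
        for s in (preprocess_spectrum(x, fp) for x in small_cohort.spectra)
        if not s.is_empty
    ]
    strain_of = {
        r.sample_id: r.strain_id for r in small_cohort.samples if not r.is_blank
    }
    nodes = cluster_spectra(filtered, ClusterParams(), sp, fp, strain_of)
    net = build_network(nodes)
    media = flag_media_nodes(net, small_cohort.samples)
    summary = attribute_groups(net, small_cohort.samples, media)
    return {
        "cohort": small_cohort,
        "nodes": nodes,
        "net": net,
        "media": media,
        "summary": summary,
    }
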