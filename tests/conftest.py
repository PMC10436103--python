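import pytest

from tcellsig import atac, deconvolution, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=7,
        n_subtypes=3,
        n_replicates_per_subtype=3,
        n_shared_sites=60,
        n_specific_sites_per_subtype=40,
        dropout_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return simulate.gen_subtype_peak_landscape(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_landscape):
    land, truth = small_landscape
    return simulate.gen_accessibility_counts(land, truth, small_config)


def run_signature_pipeline(config):
    """Landscape -> counts -> consensus -> gained -> specific -> signature."""
    land, truth = simulate.gen_subtype_peak_landscape(config)
    counts, truth = simulate.gen_accessibility_counts(land, truth, config)
    catalog = atac.merge_catalog(land)
    subtypes = sorted({p.subtype for p in land} - {simulate.EFFECTOR})
    consensus = {
        s: atac.consensus_sites([p for p in land if p.subtype == s], catalog=catalog)
        for s in subtypes
    }
    effector = atac.consensus_sites(
        [p for p in land if p.subtype == simulate.EFFECTOR], catalog=catalog
    )
    gained = {s: atac.gained_lost(c, effector)[0] for s, c in consensus.items()}
    specific = atac.subtype_specific(gained)
    signature = deconvolution.build_signature_matrix(
        specific, counts, {p.sample_id: p.subtype for p in land}
    )
    return {
        "landscape": land,
        "truth": truth,
        "counts": counts,
        "catalog": catalog,
        "consensus": consensus,
        "effector": effector,
        "gained": gained,
        "specific": specific,
        "signature": signature,
    }


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    return run_signature_pipeline(small_config)
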