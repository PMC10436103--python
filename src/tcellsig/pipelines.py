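"""End-to-end compositions of the module operations.

These wire the generators and analysis steps into the workflows the package
is built around, most importantly the synthetic-mixture validation of the
subtype deconvolution: landscape -> counts -> consensus -> gained/lost ->
subtype-specific sites -> signature matrix -> Dirichlet mixtures ->
constrained-regression deconvolution with permutation significance.
"""

from __future__ import annotations

from dataclasses import replace

from . import atac, deconvolution, simulate


def build_subtype_signature(config: simulate.SimulationConfig):
    """Run the ATAC side of the pipeline on a generated landscape.

    Returns a dict with the landscape, counts, catalog, per-subtype consensus
    and gained sets, subtype-specific sites, the signature matrix and the
    generator ground truth.
    """
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
    gained, lost = {}, {}
    for s in subtypes:
        gained[s], lost[s] = atac.gained_lost(consensus[s], effector)
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
        "lost": lost,
        "specific": specific,
        "signature": signature,
    }


def validation_experiment(
    seed: int,
    n_mixtures: int = 100,
    noise_sigma: float = 0.1,
    dirichlet_alpha: float = 1.0,
    n_permutations: int = deconvolution.DEFAULT_N_PERMUTATIONS,
    config: simulate.SimulationConfig | None = None,
) -> deconvolution.ValidationReport:
    """The synthetic-mixture validation at study conditions.

    Builds a 5-subtype signature matrix (>= 500 specific accessibility
    features per subtype) from a generated landscape, draws ``n_mixtures``
    Dirichlet(alpha) mixtures with multiplicative lognormal noise and
    deconvolves each with the NNLS engine, reporting per-mixture mean
    absolute proportion error (percentage points) and permutation p.
    """
    cfg = config if config is not None else simulate.SimulationConfig(seed=seed)
    cfg = replace(cfg, seed=seed)
    built = build_subtype_signature(cfg)
    sizes = {s: len(v) for s, v in built["specific"].items()}
    short = {s: n for s, n in sizes.items() if n < 500}
    if cfg.n_specific_sites_per_subtype >= 600 and short:
        raise RuntimeError(f"subtypes with < 500 specific features: {short}")
    return deconvolution.validate_on_synthetic(
        built["signature"],
        n_mixtures=n_mixtures,
        dirichlet_alpha=dirichlet_alpha,
        noise_sigma=noise_sigma,
        n_permutations=n_permutations,
        seed=seed,
    )
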