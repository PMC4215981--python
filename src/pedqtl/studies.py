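"""Operating-characteristic studies of the pipeline on synthetic data.

Each function runs a replicated simulation under the study conditions (65
inbred panel lines, 9 environments, variance triple (6.5, 7.3, 3.1) in
trait units squared) and measures one property of the analysis chain:
heritability recovery, null calibration of the association scan, power to
detect a planted QTL, pedigree origin-trace recovery, doubled-haploid
prediction-scheme comparison, and the SNP-to-PCR conversion rate. They are
used by the test suite and the acceptance script; all take explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, dh, pheno, primers, qtl
from .core import DHPopulation, GenotypeMatrix
from .sim import (
    SimulationConfig,
    StudyPanel,
    build_breeding_pedigree,
    make_genetic_map,
    nearest_marker,
    simulate_contig_triplet,
    simulate_dh_population,
    simulate_founders,
    simulate_pedigree_lines,
    simulate_phenotypes,
)

STUDY_VARIANCES = (6.5, 7.3, 3.1)  # (genotype, environment, residual)


def heritability_recovery(
    n_reps: int = 200,
    seed: int = 0,
    variances: tuple[float, float, float] = STUDY_VARIANCES,
    n_lines: int = 65,
    n_environments: int = 9,
) -> np.ndarray:
    """Broad-sense heritability estimates over replicated 65 x 9 trials.

    Phenotypes carry a pure polygenic line effect (no planted QTLs), so the
    true H^2 is var_g / (var_g + var_e + var_resid) — 0.385 for the study
    triple — and the ANOVA/EMS estimator should recover it on average.
    """
    vg, ve, vr = variances
    cfg = SimulationConfig(
        qtl_spec=[], kernel_locus=None, var_genotype=vg, var_environment=ve,
        var_residual=vr, n_environments=n_environments,
        lg_lengths=[10.0], n_markers_per_lg=2,
    )
    gmap = make_genetic_map(cfg)
    ids = [f"a{i:03d}" for i in range(n_lines)]
    geno = GenotypeMatrix(ids, gmap.marker_ids, np.zeros((n_lines, 2), dtype=np.int8))
    out = np.empty(n_reps)
    for r in range(n_reps):
        table = simulate_phenotypes(geno, cfg, gmap, seed=seed + r)
        vc = pheno.variance_components(pheno.two_way_anova(table, "FlYd"))
        out[r] = pheno.broad_sense_heritability(vc)
    return out


# ---------------------------------------------------------------------------
# association-scan calibration and power


def _structured_panel(seed: int, n_lg: int = 60, markers_per_lg: int = 20, n_lines: int = 65):
    """Pedigree panel + kinship + polygenic phenotype for the scan studies.

    Markers on the last 10 linkage groups drive a kinship-structured
    polygenic background (variance 5.5); together with the environment/
    residual variances this puts single-environment heritability near 0.4.
    Those background markers are excluded from testing, so every tested
    marker is null (h^2_marker = 0).
    """
    cfg = SimulationConfig(
        qtl_spec=[], kernel_locus=None, var_genotype=0.0, var_environment=7.3,
        var_residual=3.1, n_environments=9,
        lg_lengths=[150.0] * n_lg, n_markers_per_lg=markers_per_lg,
    )
    gmap = make_genetic_map(cfg)
    ped = build_breeding_pedigree(12, n_lines, seed=seed)
    founders = simulate_founders(cfg, gmap, seed=seed + 1)
    geno = simulate_pedigree_lines(ped, founders, gmap, seed=seed + 2)
    rng = np.random.default_rng(seed + 4)
    bg_prefixes = tuple(f"mLG{i}_" for i in range(n_lg - 9, n_lg + 1))
    bg_idx = [i for i, m in enumerate(geno.marker_ids) if m.startswith(bg_prefixes)]
    b = rng.normal(0.0, 1.0, len(bg_idx))
    gpoly = geno.calls[:, bg_idx].astype(float) @ b
    gpoly = (gpoly - gpoly.mean()) / (gpoly.std() or 1.0) * np.sqrt(5.5)
    table = simulate_phenotypes(geno, cfg, gmap, seed=seed + 3)
    gv = table.genotypic_values("FlYd") + pd.Series(gpoly, index=geno.accession_ids)
    test_ids = [m for m in geno.marker_ids if not m.startswith(bg_prefixes)]
    K = assoc.kinship(geno)
    return geno, gv, K, test_ids, rng


def null_scan_ks(
    n_reps: int = 50, seed: int = 0, n_null_markers: int = 1000
) -> pd.DataFrame:
    """Kolmogorov-Smirnov statistics of null-scan p-values vs uniform.

    Per replicate three scans run on the same polygenic phenotype:
    ``ks_mlm_free`` — kinship MLM on null markers drawn independently of
    the structure (pure calibration check); ``ks_mlm_structured`` /
    ``ks_naive_structured`` — kinship MLM and plain least squares on the
    pedigree-propagated markers, where the naive model's unmodelled
    relatedness shows up as inflation. Structured markers' p-values are
    mutually dependent, so their KS does not shrink with marker count even
    for a perfectly calibrated scan; the free-marker column is the one
    that measures calibration.
    """
    rows = []
    for r in range(n_reps):
        geno, gv, K, test_ids, rng = _structured_panel(seed + 1000 * r)
        n = geno.n_accessions
        freqs = rng.uniform(0.1, 0.9, n_null_markers)
        free_calls = (rng.random((n, n_null_markers)) < freqs).astype(np.int8)
        g_free = GenotypeMatrix(
            list(geno.accession_ids), [f"null{j}" for j in range(n_null_markers)], free_calls
        )
        p_free = assoc.mlm_scan(g_free, gv, K).dropna(subset=["p_value"])["p_value"]
        g_struct = geno.subset_markers(test_ids)
        p_mlm = assoc.mlm_scan(g_struct, gv, K).dropna(subset=["p_value"])["p_value"]
        eye = assoc.KinshipMatrix(list(geno.accession_ids), np.eye(n))
        p_naive = assoc.mlm_scan(g_struct, gv, eye, delta=np.inf).dropna(
            subset=["p_value"]
        )["p_value"]
        rows.append(
            {
                "ks_mlm_free": stats.kstest(p_free, "uniform").statistic,
                "ks_mlm_structured": stats.kstest(p_mlm, "uniform").statistic,
                "ks_naive_structured": stats.kstest(p_naive, "uniform").statistic,
            }
        )
    return pd.DataFrame(rows)


def planted_qtl_power(
    n_reps: int = 100,
    seed: int = 0,
    effect: float = 2.0,
    maf: float = 0.3,
    top_fraction: float = 0.01,
) -> float:
    """Fraction of replicates ranking a planted marker in the scan's top 1%.

    One marker with population MAF fixed at ``maf`` carries an additive
    effect of ``effect`` trait units on top of the kinship-structured
    polygenic background (single-environment h^2 ~ 0.4, n = 65).
    """
    hits = 0
    for r in range(n_reps):
        rep_seed = seed + 1000 * r
        geno, gv, K, test_ids, rng = _structured_panel(rep_seed)
        qm = test_ids[len(test_ids) // 2]
        j = geno.marker_ids.index(qm)
        calls = geno.calls.copy()
        calls[:, j] = (rng.random(geno.n_accessions) < maf).astype(np.int8)
        geno = GenotypeMatrix(list(geno.accession_ids), list(geno.marker_ids), calls)
        gv = gv + effect * pd.Series(calls[:, j], index=geno.accession_ids)
        K = assoc.kinship(geno)
        scan = assoc.mlm_scan(geno.subset_markers(test_ids), gv, K).dropna(
            subset=["p_value"]
        )
        p_marker = float(scan.set_index("marker_id")["p_value"][qm])
        rank = int((scan["p_value"] < p_marker).sum())
        if rank < max(1, int(top_fraction * len(scan))):
            hits += 1
    return hits / n_reps


def null_ttest_ks(
    n_reps: int = 50, seed: int = 0, n_lines: int = 150, n_markers: int = 1000
) -> np.ndarray:
    """KS statistics of allele-mean t-test p-values in null DH populations.

    Markers are unlinked (one per linkage group), the trait is pure noise,
    so every p-value is null; the pooled t-test should be uniform.
    """
    cfg = SimulationConfig(
        qtl_spec=[], kernel_locus=None, var_genotype=0, var_environment=0,
        var_residual=1.0, n_environments=1,
        lg_lengths=[1.0] * n_markers, n_markers_per_lg=1,
    )
    gmap = make_genetic_map(cfg)
    out = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        p1 = np.zeros(n_markers, dtype=np.int8)
        p2 = np.ones(n_markers, dtype=np.int8)
        pop = simulate_dh_population(p1, p2, n_lines, gmap, seed=seed + r, name="DH")
        pop.phenotypes = pd.Series(
            rng.normal(64.0, 1.0, n_lines), index=pop.genotypes.accession_ids
        )
        ps = []
        for m in pop.genotypes.marker_ids:
            res = dh.allele_mean_test(pop, m)
            if np.isfinite(res.p):
                ps.append(res.p)
        out[r] = stats.kstest(ps, "uniform").statistic
    return out


# ---------------------------------------------------------------------------
# origin tracing


def origin_trace_recovery(
    n_reps: int = 100,
    seed: int = 0,
    block_markers: int = 5,
    carrier_threshold: float = 0.9,
) -> float:
    """Fraction of tagged simulations recovering the introducing founder.

    A tight 5-marker block (0.02 cM spacing, so it transmits intact) gets a
    distinct haplotype per founder; allele origins are tracked through the
    pedigree, the focal line's true introducing founder is read off the
    tags, and origin tracing from block similarities must name it among the
    source ancestors.
    """
    spacing = 0.02
    cfg = SimulationConfig(
        qtl_spec=[], kernel_locus=None, var_genotype=0, var_environment=0,
        var_residual=1.0, n_environments=1,
        lg_lengths=[(block_markers - 1) * spacing, 50.0],
        n_markers_per_lg=block_markers,
    )
    gmap = make_genetic_map(cfg)
    block_ids = [m for m in gmap.marker_ids if m.startswith("mLG1_")]
    hits = 0
    n_eval = 0
    for r in range(n_reps):
        rep_seed = seed + 100 * r
        ped = build_breeding_pedigree(12, 40, seed=rep_seed)
        founders = simulate_founders(cfg, gmap, seed=rep_seed + 1)
        calls = founders.calls.copy()
        # give every founder a distinct block haplotype (binary code)
        for i in range(calls.shape[0]):
            code = [(i >> b) & 1 for b in range(block_markers)]
            for k, m in enumerate(block_ids):
                calls[i, founders.marker_ids.index(m)] = code[k]
        founders = GenotypeMatrix(list(founders.accession_ids), list(founders.marker_ids), calls)
        geno, origins = simulate_pedigree_lines(
            ped, founders, gmap, seed=rep_seed + 2, return_origins=True
        )
        focal_i = geno.accession_index("focal")
        block_cols = [geno.marker_ids.index(m) for m in block_ids]
        focal_orig = origins[focal_i, block_cols]
        if len(set(focal_orig)) != 1:
            continue  # block recombined inside the focal line; tag undefined
        true_founder = founders.accession_ids[int(focal_orig[0])]
        n_eval += 1
        block = qtl.LDBlock("LG1", 0.0, (block_markers - 1) * spacing, block_ids, True)
        sims = qtl.block_similarity(geno, block, "focal")
        origin = qtl.trace_origin(ped, sims, "focal", carrier_threshold=carrier_threshold)
        if true_founder in origin.source_ancestors:
            hits += 1
    return hits / max(n_eval, 1)


# ---------------------------------------------------------------------------
# primer conversion


def primer_conversion(
    n_triplets: int = 200,
    seed: int = 0,
    length: int = 1000,
    divergence: float = 0.03,
) -> tuple[float, bool]:
    """(design-and-validate pass rate, band contract held on every pass).

    The band contract is the genotyping read-out: two bands when the
    template matches the reaction's ASP allele, one when it does not.
    """
    n_pass = 0
    contract_ok = True
    for i in range(n_triplets):
        triplet = simulate_contig_triplet(
            length, divergence, length // 2, seed=seed + i
        )
        try:
            ps = primers.design_primer_set(triplet, marker_id=f"snp{i}")
        except primers.DesignError:
            continue
        report = primers.validate_primer_set(ps, triplet)
        if report.passed:
            n_pass += 1
            ref, alt = triplet.target_snp[2], triplet.target_snp[3]
            for rx_allele in (ref, alt):
                for tpl_allele in (ref, alt):
                    bp = report.patterns[f"ASP-{rx_allele}_on_allele-{tpl_allele}"]
                    expected = 2 if rx_allele == tpl_allele else 1
                    if bp.n_bands != expected:
                        contract_ok = False
    return n_pass / n_triplets, contract_ok


# ---------------------------------------------------------------------------
# DH prediction schemes


def dh_prediction_comparison(
    n_reps: int = 100,
    seed: int = 0,
    n_lines: int = 150,
    n_markers: int = 5,
    sigma: float = 1.5,
) -> pd.DataFrame:
    """Per-population vs combined regression when marker effects differ.

    Three DH populations segregate for the same markers but with
    population-specific effect sizes (different genetic backgrounds); the
    per-population ("each") scheme should beat the combined ("total")
    scheme on pooled prediction accuracy. Returns per-replicate r values.
    """
    cfg = SimulationConfig(
        qtl_spec=[], kernel_locus=None, lg_lengths=[30.0] * n_markers,
        n_markers_per_lg=1, var_genotype=0, var_environment=0, var_residual=1.0,
        n_environments=1,
    )
    gmap = make_genetic_map(cfg)
    rows = []
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        pops = []
        for k in range(3):
            p1 = np.ones(n_markers, dtype=np.int8)
            p2 = np.zeros(n_markers, dtype=np.int8)
            pop = simulate_dh_population(
                p1, p2, n_lines, gmap, seed=seed + r * 10 + k, name=f"DH{k + 1}",
                parent_ids=("focal", f"other{k + 1}"),
            )
            effects = rng.uniform(0.0, 2.5, n_markers)  # background-specific
            y = 64.0 + pop.genotypes.calls.astype(float) @ effects
            y = y + rng.normal(0, sigma, n_lines)
            pop.phenotypes = pd.Series(y, index=pop.genotypes.accession_ids)
            pops.append(pop)
        markers = list(gmap.marker_ids)
        _, r_each = dh.pooled_prediction_accuracy(pops, markers, per_population=True)
        _, r_total = dh.pooled_prediction_accuracy(pops, markers, per_population=False)
        rows.append({"r_each": r_each, "r_total": r_total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end synthetic study


def panel_association_study(panel: StudyPanel, q_threshold: float = 0.5) -> dict:
    """Run the full association workflow on a synthetic panel.

    Filter (MAF >= 0.1, redundancy), kNN-impute, kinship, kernel-covariate
    MLM scan, Storey FDR, QTL classification. Returns the intermediate
    tables plus summary counts.
    """
    g = assoc.filter_markers(panel.genotypes, 0.1, gmap=panel.gmap)
    g = assoc.knn_impute(g)
    K = assoc.kinship(g)
    gv = panel.phenotypes.genotypic_values("FlYd")
    scan = assoc.mlm_scan(g, gv, K, covariates=panel.kernel_type)
    sig = assoc.mta_table(scan, panel.gmap, q_threshold=q_threshold)
    qtls, unlocated = qtl.classify_mtas(sig)
    planted = {m: panel.gmap.position_of(m) for m in panel.qtl_markers}
    if panel.config.kernel_locus is not None:
        km = nearest_marker(panel.gmap, *panel.config.kernel_locus)
        planted[km] = panel.gmap.position_of(km)

    def _near_planted(marker_id: str, window_cm: float = 10.0) -> bool:
        lg, pos = panel.gmap.position_of(marker_id)
        return any(plg == lg and abs(ppos - pos) <= window_cm for plg, ppos in planted.values())

    near = [_near_planted(m) for m in sig["marker_id"]]
    return {
        "genotypes": g,
        "kinship": K,
        "scan": scan,
        "significant": sig,
        "qtls": qtls,
        "unlocated": unlocated,
        "n_significant": len(sig),
        "n_qtls": len(qtls),
        "frac_near_planted": float(np.mean(near)) if near else float("nan"),
    }


def panel_dh_validation(
    panel: StudyPanel, seed: int, n_pops: int = 3, n_lines: int = 150
) -> dict:
    """Cross the focal line to segregating panel mates and validate QTLs.

    Mates are the panel lines differing from the focal line at the most
    planted QTL markers, so the crosses segregate for the trait. DH traits
    use the plot residual variance only (unreplicated single-season trial,
    as in the validation design). Returns populations, the allele-mean
    validation table and the two pooled prediction accuracies.
    """
    cfg = panel.config
    geno = panel.genotypes
    focal = geno.calls[geno.accession_index(panel.focal_id)].copy()
    focal[focal < 0] = 0
    qtl_cols = [geno.marker_index(m) for m in panel.qtl_markers]
    others = [a for a in geno.accession_ids if a != panel.focal_id]
    n_poly = {
        a: int((geno.calls[geno.accession_index(a), qtl_cols] != focal[qtl_cols]).sum())
        for a in others
    }
    mates = sorted(others, key=lambda a: (-n_poly[a], a))[:n_pops]
    trait_cfg = SimulationConfig(
        qtl_spec=cfg.qtl_spec, kernel_locus=cfg.kernel_locus,
        kernel_locus_effect=cfg.kernel_locus_effect, var_genotype=0.0,
        var_environment=0.0, var_residual=cfg.var_residual, n_environments=1,
        lg_lengths=cfg.lg_lengths, n_markers_per_lg=cfg.n_markers_per_lg,
    )
    pops: list[DHPopulation] = []
    for k, mate in enumerate(mates):
        other = geno.calls[geno.accession_index(mate)].copy()
        other[other < 0] = 0
        pop = simulate_dh_population(
            focal, other, n_lines, panel.gmap, seed=seed + 10 * k,
            name=f"DH{k + 1}", parent_ids=(panel.focal_id, mate),
        )
        ph = simulate_phenotypes(pop.genotypes, trait_cfg, panel.gmap, seed=seed + 10 * k + 5)
        pop.phenotypes = ph.genotypic_values("FlYd")
        pops.append(pop)
    markers = panel.qtl_markers[:8]
    table = dh.validation_table(pops, markers)
    _, r_each = dh.pooled_prediction_accuracy(pops, markers, per_population=True)
    _, r_total = dh.pooled_prediction_accuracy(pops, markers, per_population=False)
    return {
        "populations": pops,
        "markers": markers,
        "validation": table,
        "r_each": r_each,
        "r_total": r_total,
    }
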