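"""Synthetic methylation cohorts with the structure the pipeline assumes.

The generator emulates what matters statistically about an FFPE carcinoma
cohort profiled on a methylation array, at desk scale:

* six organ classes with the real cohort's class imbalance (down-scaled),
* organ-specific mean shifts confined to disjoint mQTL probe blocks,
  defined on the M-scale and back-transformed so beta stays in (0, 1),
* per-batch additive M-scale distortions (processing-year batches),
* beta-distributed measurement noise with tunable concentration,
* uniform missingness, and sex-chromosome / SNP-flagged probes so the QC
  filters have something to remove.

It does not attempt genomic CpG autocorrelation, probe-chemistry effects or
FFPE degradation; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    BetaMatrix,
    CLASSES,
    MQTLCatalog,
    ProbeAnnotations,
    SampleSheet,
    ValidationError,
)
from .preprocess import beta_to_m, m_to_beta

import pandas as pd

#: ~3.4x down-scaled version of the real cohort's class counts
#: (breast 143, gyn 91, testis 86, lung 85, kidney 84, colon 20 of 509).
DEFAULT_N_PER_CLASS: dict[str, int] = {
    "breast": 42, "gyn": 27, "testis": 26, "lung": 25, "kidney": 25, "colon": 6,
}


@dataclass
class SimConfig:
    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    n_probes: int = 2000
    mqtl_per_class: int = 100
    #: organ effect magnitude on the M-scale (log2 odds of methylation)
    effect_delta: float = 1.5
    baseline_mean_range: tuple[float, float] = (0.1, 0.9)
    #: Beta-distribution concentration; larger = less measurement noise
    precision_nu: float = 50.0
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    #: explicit per-batch M-scale shifts; overrides the sampled shifts
    batch_shift_values: tuple[float, ...] | None = None
    missing_rate: float = 0.01
    frac_sex_probes: float = 0.05
    frac_snp_probes: float = 0.02
    metastasis_rate: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_class.values()):
            raise ValidationError("n_per_class counts must be positive")
        bad = sorted(set(self.n_per_class) - set(CLASSES))
        if bad:
            raise ValidationError(f"unknown organs in n_per_class: {bad}")
        for name in ("missing_rate", "frac_sex_probes", "frac_snp_probes", "metastasis_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.effect_delta < 0:
            raise ValidationError("effect_delta must be >= 0")
        n_sex = int(round(self.frac_sex_probes * self.n_probes))
        n_snp = int(round(self.frac_snp_probes * self.n_probes))
        needed = self.mqtl_per_class * len(self.n_per_class) + n_sex + n_snp
        if needed > self.n_probes:
            raise ValidationError(
                f"n_probes={self.n_probes} too small for {needed} "
                f"mQTL + sex + SNP probes"
            )


def simulate_cohort(
    cfg: SimConfig | None = None,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotations, MQTLCatalog, dict]:
    """Draw one synthetic cohort; returns all four artifacts plus the truth.

    Generative model, per probe j and sample i of organ o in batch b:
    M_ij = logit2(mu_j) + s_j*delta*[j in block(o)] + gamma_b, observed
    beta_ij ~ Beta(mu'_ij*nu, (1-mu'_ij)*nu) with mu' = expit2(M), then
    masked missing uniformly at ``missing_rate``. The truth record keeps
    every latent quantity for recovery tests.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    organs = [o for o in CLASSES if o in cfg.n_per_class]
    n_samples = sum(cfg.n_per_class[o] for o in organs)
    n_probes = cfg.n_probes
    probe_ids = [f"cg{j:08d}" for j in range(n_probes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    # carve probe roles out of a random permutation: sex / snp / mQTL blocks
    n_sex = int(round(cfg.frac_sex_probes * n_probes))
    n_snp = int(round(cfg.frac_snp_probes * n_probes))
    perm = rng.permutation(n_probes)
    sex_idx = perm[:n_sex]
    snp_idx = perm[n_sex : n_sex + n_snp]
    blocks: dict[str, np.ndarray] = {}
    cursor = n_sex + n_snp
    for o in organs:
        blocks[o] = np.sort(perm[cursor : cursor + cfg.mqtl_per_class])
        cursor += cfg.mqtl_per_class

    lo, hi = cfg.baseline_mean_range
    mu = rng.uniform(lo, hi, size=n_probes)
    m0 = beta_to_m(mu)
    sign = rng.choice([-1.0, 1.0], size=n_probes)

    labels = [o for o in organs for _ in range(cfg.n_per_class[o])]
    batch_names = [f"batch{b}" for b in range(cfg.n_batches)]
    batch_idx = np.arange(n_samples) % cfg.n_batches  # stripes organs evenly
    if cfg.batch_shift_values is not None:
        if len(cfg.batch_shift_values) != cfg.n_batches:
            raise ValidationError("batch_shift_values length must equal n_batches")
        gamma = np.asarray(cfg.batch_shift_values, dtype=np.float64)
    else:
        gamma = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_batches)

    m_mean = np.tile(m0[:, None], (1, n_samples))
    for o in organs:
        cols = [i for i, l in enumerate(labels) if l == o]
        rows = blocks[o]
        m_mean[np.ix_(rows, cols)] += sign[rows, None] * cfg.effect_delta
    m_mean += gamma[batch_idx][None, :]

    mu_shifted = m_to_beta(m_mean)
    a = mu_shifted * cfg.precision_nu
    b = (1.0 - mu_shifted) * cfg.precision_nu
    values = rng.beta(a, b)
    values = np.clip(values, 1e-9, 1.0 - 1e-9)

    mask = rng.random(values.shape) < cfg.missing_rate
    values[mask] = np.nan

    chrom = np.empty(n_probes, dtype=object)
    autosomes = [f"chr{c}" for c in range(1, 23)]
    chrom[:] = rng.choice(autosomes, size=n_probes)
    chrom[sex_idx] = rng.choice(["chrX", "chrY"], size=n_sex)
    snp_flag = np.zeros(n_probes, dtype=bool)
    snp_flag[snp_idx] = True
    manifest = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": rng.integers(1, 2_000_000_00, size=n_probes),
            "snp_overlap": snp_flag,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    bm = BetaMatrix(probe_ids, sample_ids, values)
    sheet = SampleSheet(
        sample_ids,
        labels,
        [batch_names[b] for b in batch_idx],
        list(rng.random(n_samples) < cfg.metastasis_rate),
    )
    ann = ProbeAnnotations(manifest)
    catalog = MQTLCatalog(
        {o: frozenset(probe_ids[j] for j in blocks[o]) for o in organs}
    )
    truth = {
        "blocks": {o: [probe_ids[j] for j in blocks[o]] for o in organs},
        "sign": {probe_ids[j]: float(sign[j]) for o in organs for j in blocks[o]},
        "baseline_mu": dict(zip(probe_ids, map(float, mu))),
        "gamma": dict(zip(batch_names, map(float, gamma))),
        "batch_of": dict(zip(sample_ids, (batch_names[b] for b in batch_idx))),
        "n_missing": int(mask.sum()),
        "sex_probes": [probe_ids[j] for j in np.sort(sex_idx)],
        "snp_probes": [probe_ids[j] for j in np.sort(snp_idx)],
    }
    return bm, sheet, ann, catalog, truth


def batch_gap(m_values: np.ndarray, batches: list[str]) -> float:
    """Mean absolute per-probe gap between the first two batch means."""
    levels = sorted(set(batches))
    cols = {lev: [j for j, b in enumerate(batches) if b == lev] for lev in levels}
    a = np.nanmean(m_values[:, cols[levels[0]]], axis=1)
    b = np.nanmean(m_values[:, cols[levels[1]]], axis=1)
    return float(np.nanmean(np.abs(a - b)))


def benchmark_suite(seed: int = 0, epochs: int = 50) -> dict:
    """Run the canonical end-to-end scenarios and record their outcomes.

    Failures are recorded in the returned table, never raised, so the suite
    always produces a complete machine-readable record.
    """
    from .evaluate import compute_metrics, cross_validate
    from .features import FeatureSelectionConfig
    from .network import NetworkConfig
    from .preprocess import combat_adjust, preprocess_cohort

    results: dict[str, dict] = {}

    # -- structural assertions on the default cohort -------------------------
    cfg = SimConfig(seed=seed)
    bm, sheet, ann, catalog, truth = simulate_cohort(cfg)
    all_blocks = [set(v) for v in truth["blocks"].values()]
    disjoint = all(
        not (a & b) for i, a in enumerate(all_blocks) for b in all_blocks[i + 1 :]
    )
    finite = bm.values[~np.isnan(bm.values)]
    results["structure"] = {
        "passed": bool(
            bm.values.shape == (cfg.n_probes, sheet.n_samples)
            and disjoint
            and (finite > 0).all()
            and (finite < 1).all()
        ),
        "n_probes": bm.n_probes,
        "n_samples": bm.n_samples,
        "missing_frac": float(np.isnan(bm.values).mean()),
    }

    # -- separable-cohort recovery -------------------------------------------
    net = NetworkConfig(epochs=epochs, seed=seed)
    clean, kept_sheet, _ = preprocess_cohort(bm, sheet, ann)
    cv = cross_validate(clean, kept_sheet, catalog,
                        FeatureSelectionConfig(), net, k=10, seed=seed)
    top2_ge_top1 = all(
        m["top2_accuracy"] >= m["accuracy"] for m in cv.fold_metrics
    )
    results["separable_recovery"] = {
        "passed": bool(cv.mean_accuracy >= 0.95 and top2_ge_top1),
        "mean_accuracy": cv.mean_accuracy,
        "mean_top2_accuracy": cv.mean_top2_accuracy,
        "mean_macro_f1": cv.mean_macro_f1,
    }

    # -- null-label chance level ---------------------------------------------
    null_cfg = SimConfig(seed=seed, effect_delta=0.0)
    bm0, sheet0, ann0, catalog0, _ = simulate_cohort(null_cfg)
    clean0, kept0, _ = preprocess_cohort(bm0, sheet0, ann0)
    cv0 = cross_validate(clean0, kept0, catalog0,
                         FeatureSelectionConfig(), net, k=10, seed=seed)
    results["null_control"] = {
        "passed": bool(abs(cv0.mean_accuracy - 1.0 / 6.0) <= 0.10),
        "mean_accuracy": cv0.mean_accuracy,
    }

    # -- batch-correction recovery -------------------------------------------
    shift_cfg = SimConfig(seed=seed, batch_shift_values=(0.0, 1.0), missing_rate=0.0)
    bms, sheets, _, _, _ = simulate_cohort(shift_cfg)
    m = beta_to_m(bms.values)
    gap_before = batch_gap(m, sheets.batches)
    adjusted = combat_adjust(m, sheets.batches)
    gap_after = batch_gap(adjusted, sheets.batches)
    reduction = gap_before / gap_after if gap_after > 0 else float("inf")
    results["batch_correction"] = {
        "passed": bool(reduction >= 5.0),
        "gap_before": gap_before,
        "gap_after": gap_after,
        "reduction_factor": reduction,
    }

    # -- metric oracle spot check ---------------------------------------------
    rng = np.random.default_rng(seed)
    ok = True
    for _ in range(20):
        n = int(rng.integers(5, 40))
        p = rng.dirichlet(np.ones(6), size=n)
        truth_labels = [CLASSES[i] for i in rng.integers(0, 6, size=n)]
        got = compute_metrics(p, truth_labels, CLASSES)
        correct = sum(
            CLASSES[int(np.argmax(row))] == t for row, t in zip(p, truth_labels)
        )
        ok = ok and abs(got["accuracy"] - correct / n) < 1e-12
    results["metric_oracles"] = {"passed": bool(ok)}

    results["all_passed"] = {"passed": all(v["passed"] for v in results.values())}
    return results
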