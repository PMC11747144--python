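"""Probe/sample QC, beta<->M transforms and empirical-Bayes batch correction.

The pipeline ingests *already normalized* beta matrices: raw-intensity
normalization (funnorm and friends) needs IDAT control probes that a beta
matrix no longer carries, so it is an upstream responsibility and is
deliberately not reimplemented here. Detection p-values are likewise
unavailable downstream of normalization; "poorly performing" probes are
operationalized as probes with a high missing fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import BetaMatrix, ProbeAnnotations, SEX_CHROMOSOMES, ValidationError


@dataclass
class QCParams:
    """Quality-control thresholds for probe and sample filtering."""

    max_probe_missing_frac: float = 0.10
    max_sample_missing_frac: float = 0.10
    drop_sex_chromosomes: bool = True
    drop_snp_probes: bool = True
    mvalue_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_probe_missing_frac", "max_sample_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.mvalue_epsilon < 0.5:
            raise ValidationError("mvalue_epsilon must be in (0, 0.5)")


@dataclass
class FilterReport:
    """Audit trail for QC: how many probes/samples each rule removed."""

    probes_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: int = 0
    probes_retained: int = 0
    samples_retained: int = 0

    @property
    def total_probes_removed(self) -> int:
        return sum(self.probes_removed.values())


def filter_probes(
    bm: BetaMatrix, ann: ProbeAnnotations, qc: QCParams | None = None
) -> tuple[BetaMatrix, FilterReport]:
    """Remove sex-chromosome, SNP-overlapping and high-missingness probes.

    A probe is attributed to the *first* rule it fails, in the fixed order
    unannotated -> sex -> snp -> missingness, so reports are reproducible.
    Probes absent from the manifest are treated as failing QC.
    """
    qc = qc or QCParams()
    frame = ann.frame
    missing_frac = np.isnan(bm.values).mean(axis=1)
    removed = {"unannotated": 0, "sex": 0, "snp": 0, "missing": 0}
    keep: list[int] = []
    known = set(map(str, frame.index))
    chrom = frame["chromosome"]
    snp = frame["snp_overlap"]
    for i, probe in enumerate(bm.probe_ids):
        if probe not in known:
            removed["unannotated"] += 1
        elif qc.drop_sex_chromosomes and chrom[probe] in SEX_CHROMOSOMES:
            removed["sex"] += 1
        elif qc.drop_snp_probes and bool(snp[probe]):
            removed["snp"] += 1
        elif missing_frac[i] > qc.max_probe_missing_frac:
            removed["missing"] += 1
        else:
            keep.append(i)
    if not keep:
        raise ValidationError("empty matrix after QC: all probes removed")
    out = BetaMatrix(
        [bm.probe_ids[i] for i in keep], list(bm.sample_ids), bm.values[keep]
    )
    report = FilterReport(
        probes_removed=removed,
        probes_retained=len(keep),
        samples_retained=bm.n_samples,
    )
    return out, report


def filter_samples(
    bm: BetaMatrix, qc: QCParams | None = None
) -> tuple[BetaMatrix, FilterReport]:
    """Drop samples whose missing fraction exceeds the QC threshold."""
    qc = qc or QCParams()
    missing_frac = np.isnan(bm.values).mean(axis=0)
    keep = [j for j in range(bm.n_samples) if missing_frac[j] <= qc.max_sample_missing_frac]
    if not keep:
        raise ValidationError("empty matrix after QC: all samples removed")
    out = BetaMatrix(
        list(bm.probe_ids), [bm.sample_ids[j] for j in keep], bm.values[:, keep]
    )
    report = FilterReport(
        samples_removed=bm.n_samples - len(keep),
        probes_retained=bm.n_probes,
        samples_retained=len(keep),
    )
    return out, report


# ---------------------------------------------------------------------------
# beta <-> M transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """M = log2(b' / (1 - b')) with b' clipped to [epsilon, 1 - epsilon].

    The logit-2 transform stabilizes variance near the 0/1 boundaries;
    NaN entries pass through unchanged.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValidationError("epsilon must be in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=np.float64), epsilon, 1.0 - epsilon)
    with np.errstate(invalid="ignore"):
        m = np.log2(b / (1.0 - b))
    m = np.where(np.isnan(np.asarray(beta, dtype=np.float64)), np.nan, m)
    return m


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse transform b = 2^M / (1 + 2^M); NaN passes through."""
    m = np.asarray(m, dtype=np.float64)
    with np.errstate(over="ignore", invalid="ignore"):
        # expit form is overflow-safe for large |M|
        b = np.where(m >= 0, 1.0 / (1.0 + 2.0 ** (-m)),
                     2.0 ** np.minimum(m, 0) / (1.0 + 2.0 ** np.minimum(m, 0)))
    return np.where(np.isnan(m), np.nan, b)


# ---------------------------------------------------------------------------
# ComBat batch correction
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m * m) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative EB solution for batch location/scale (parametric priors)."""
    n = (~np.isnan(sdat)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    m_values: np.ndarray,
    batches: Sequence[str],
    parametric: bool = True,
) -> np.ndarray:
    """Empirical-Bayes location/scale batch adjustment (the ComBat model).

    Per probe, batch means and variances are standardized away after
    shrinking the per-batch estimates toward batch-level priors (normal on
    location, inverse-gamma on scale in the parametric variant). Missing
    entries are imputed with the probe mean for estimation and re-masked in
    the output. A single batch passes through unchanged.

    Parameters
    ----------
    m_values : probes x samples array, M-scale recommended.
    batches : per-sample batch identifiers; every batch needs >= 2 samples.
    parametric : use parametric EB priors (non-parametric not implemented;
        kept for interface completeness).
    """
    x = np.asarray(m_values, dtype=np.float64)
    batches = [str(b) for b in batches]
    if x.ndim != 2 or x.shape[1] != len(batches):
        raise ValidationError("batches length must equal the number of samples")
    levels = sorted(set(batches))
    if len(levels) == 1:
        return x.copy()
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is implemented")
    groups = {lev: np.array([j for j, b in enumerate(batches) if b == lev]) for lev in levels}
    for lev, idx in groups.items():
        if idx.size < 2:
            raise ValidationError(f"batch {lev!r} has fewer than 2 samples")

    mask = np.isnan(x)
    if mask.any():
        probe_mean = np.nanmean(np.where(mask, np.nan, x), axis=1)
        probe_mean = np.nan_to_num(probe_mean)  # all-missing probe -> 0
        x = np.where(mask, probe_mean[:, None], x)

    n_array = x.shape[1]
    n_batches = np.array([groups[lev].size for lev in levels], dtype=float)
    # per-probe per-batch means (the OLS fit for a pure batch design)
    b_hat = np.column_stack([x[:, groups[lev]].mean(axis=1) for lev in levels])
    grand_mean = b_hat @ (n_batches / n_array)
    fitted = np.empty_like(x)
    for bi, lev in enumerate(levels):
        fitted[:, groups[lev]] = b_hat[:, [bi]]
    var_pooled = ((x - fitted) ** 2).sum(axis=1) / n_array
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    sd = np.sqrt(var_pooled)[:, None]
    s_data = (x - grand_mean[:, None]) / sd

    gamma_star = np.empty_like(b_hat)
    delta_star = np.empty_like(b_hat)
    for bi, lev in enumerate(levels):
        cols = groups[lev]
        g_hat = s_data[:, cols].mean(axis=1)
        d_hat = s_data[:, cols].var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(s_data[:, cols], g_hat, d_hat, g_bar, t2, a, b)
        gamma_star[:, bi] = g_star
        delta_star[:, bi] = d_star

    adjusted = np.empty_like(s_data)
    for bi, lev in enumerate(levels):
        cols = groups[lev]
        adjusted[:, cols] = (s_data[:, cols] - gamma_star[:, [bi]]) / np.sqrt(
            delta_star[:, [bi]]
        )
    out = adjusted * sd + grand_mean[:, None]
    out[mask] = np.nan
    return out


def impute_probe_means(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaNs with per-probe means; returns (imputed, means)."""
    means = np.nanmean(values, axis=1)
    means = np.nan_to_num(means, nan=0.5)
    out = np.where(np.isnan(values), means[:, None], values)
    return out, means


def preprocess_cohort(bm, sheet, ann, qc: QCParams | None = None,
                      correction_scale: str = "m"):
    """QC filters followed by batch correction: the full preprocessing chain.

    Correction runs on the M-scale by default (variance-stabilized) and is
    back-transformed to beta; ``correction_scale="beta"`` corrects the beta
    values directly. Returns (corrected BetaMatrix, report dict).
    """
    from .io import BetaMatrix  # local import to avoid cycle at module load

    qc = qc or QCParams()
    if correction_scale not in {"m", "beta"}:
        raise ValidationError(f"unknown correction_scale {correction_scale!r}")
    bm, probe_report = filter_probes(bm, ann, qc)
    bm, sample_report = filter_samples(bm, qc)
    kept_sheet = sheet.subset(bm.sample_ids)
    if correction_scale == "m":
        m = beta_to_m(bm.values, qc.mvalue_epsilon)
        m = combat_adjust(m, kept_sheet.batches)
        values = m_to_beta(m)
    else:
        values = combat_adjust(bm.values, kept_sheet.batches)
        values = np.clip(values, 0.0, 1.0)
    out = BetaMatrix(list(bm.probe_ids), list(bm.sample_ids), values)
    report = {
        "probes_removed": probe_report.probes_removed,
        "samples_removed": sample_report.samples_removed,
        "probes_retained": out.n_probes,
        "samples_retained": out.n_samples,
        "correction_scale": correction_scale,
    }
    return out, kept_sheet, report
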