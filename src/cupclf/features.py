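"""Feature selection: mQTL restriction, then top-K most-variable probes.

The classifier never sees the whole array: probes are first restricted to
the union of organ-specific mQTL sets (methylation loci whose levels carry
a conserved organ-of-origin signature), then capped at the ``top_k`` probes
with the largest beta-value variance. The frozen, ordered probe list is
part of the trained model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import BetaMatrix, CLASSES, MQTLCatalog, ValidationError

log = logging.getLogger(__name__)


@dataclass
class FeatureSelectionConfig:
    organs: tuple[str, ...] = CLASSES
    top_k: int = 20000
    #: "training-only" recomputes variance inside each training split
    #: (no leakage); "full-cohort" ranks on all samples, which is
    #: optimistic for held-out metrics.
    variance_scope: str = "training-only"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not self.organs:
            raise ValidationError("organs must be non-empty")
        if self.variance_scope not in {"training-only", "full-cohort"}:
            raise ValidationError(f"unknown variance_scope {self.variance_scope!r}")


def restrict_to_mqtl(
    bm: BetaMatrix, catalog: MQTLCatalog, organs: tuple[str, ...] = CLASSES
) -> BetaMatrix:
    """Keep only probes in the union of the requested organs' mQTL sets.

    The original probe order of ``bm`` is preserved.
    """
    union = catalog.union_for(organs)
    keep = [p for p in bm.probe_ids if p in union]
    if not keep:
        raise ValidationError("no mQTL probes present on array")
    absent = len(union) - len(keep)
    if absent:
        warnings.warn(
            f"{absent} mQTL catalog probes are not present in the matrix",
            stacklevel=2,
        )
    log.info("mQTL restriction: %d of %d probes retained", len(keep), bm.n_probes)
    if len(keep) == bm.n_probes:
        return bm
    return bm.subset_probes(keep)


def probe_variances(bm: BetaMatrix) -> np.ndarray:
    """Per-probe sample variance (ddof=1) over non-missing beta values.

    Probes with fewer than 2 non-missing values get variance 0.
    """
    v = bm.values
    n_obs = (~np.isnan(v)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(v, axis=1, ddof=1)
    return np.where(n_obs < 2, 0.0, np.nan_to_num(var))


def select_top_variable(bm: BetaMatrix, k: int) -> list[str]:
    """Return the k probe ids with the largest variance, deterministically.

    Ties are broken lexicographically by probe id, so the result does not
    depend on the input row order. If ``k >= n_probes`` all probes are
    returned, still ordered by (variance desc, id asc).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if bm.n_probes == 0:
        raise ValidationError("empty matrix")
    var = probe_variances(bm)
    order = sorted(range(bm.n_probes), key=lambda i: (-var[i], bm.probe_ids[i]))
    return [bm.probe_ids[i] for i in order[:k]]


def select_features(
    bm: BetaMatrix, catalog: MQTLCatalog, cfg: FeatureSelectionConfig
) -> list[str]:
    """mQTL restriction followed by top-K variance ranking, in one call."""
    restricted = restrict_to_mqtl(bm, catalog, cfg.organs)
    return select_top_variable(restricted, cfg.top_k)
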