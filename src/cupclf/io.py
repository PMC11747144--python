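"""Readers, writers and validation for the pipeline's on-disk artifacts.

Canonical formats (all plain text):

* beta matrix  — TSV/CSV, row 1 = sample ids, column 1 = probe ids
  (probes x samples); empty cells or ``NA`` denote missing values,
  ``NA`` is written on output.
* sample sheet — CSV with columns ``sample_id,label,batch,is_metastasis``
  (``label`` may be absent for inference-only cohorts).
* probe manifest — CSV with columns ``probe_id,chromosome,position,snp_overlap``.
* mQTL catalog — long-format CSV with columns ``organ,probe_id``.
* trained model — a directory holding a JSON manifest plus one raw
  little-endian float32 binary per weight array (language-portable, no
  framework checkpoint).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The six BLOCKT organ classes, in prediction-report column order.
CLASSES: tuple[str, ...] = ("breast", "lung", "gyn", "colon", "kidney", "testis")

#: Chromosome vocabulary for probe manifests.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

SEX_CHROMOSOMES: frozenset[str] = frozenset({"chrX", "chrY"})

_NA_TOKENS = ("", "NA")


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))[:10]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta fractions in [0, 1].

    Missing entries are NaN. Validation runs on construction.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float64, shape (n_probes, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe ids")
        _check_unique(self.sample_ids, "sample ids")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"probe {self.probe_ids[i]!r}, sample {self.sample_ids[j]!r} "
                f"({int(bad.sum())} offending cells total)"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class SampleSheet:
    """Per-sample metadata: organ label, processing batch, metastasis flag."""

    sample_ids: list[str]
    labels: list[str] | None  # None => inference-only sheet
    batches: list[str]
    is_metastasis: list[bool]

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample ids")
        n = len(self.sample_ids)
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValidationError("label column length mismatch")
            bad = sorted({l for l in self.labels if l not in CLASSES})
            if bad:
                raise ValidationError(
                    f"unknown organ labels {bad}; allowed labels are {list(CLASSES)}"
                )
        if len(self.batches) != n or len(self.is_metastasis) != n:
            raise ValidationError("metadata column length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def label_of(self) -> dict[str, str]:
        if self.labels is None:
            raise ValidationError("sample sheet has no labels (inference-only)")
        return dict(zip(self.sample_ids, self.labels))

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return SampleSheet(
            [self.sample_ids[i] for i in rows],
            None if self.labels is None else [self.labels[i] for i in rows],
            [self.batches[i] for i in rows],
            [self.is_metastasis[i] for i in rows],
        )


@dataclass
class ProbeAnnotations:
    """Array manifest: chromosome, position and SNP-overlap flag per probe."""

    frame: pd.DataFrame  # index probe_id; columns chromosome, position, snp_overlap

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise ValidationError(
                f"duplicate probe ids in manifest: "
                f"{sorted(f.index[f.index.duplicated()].unique())[:10]}"
            )
        bad = sorted(set(f["chromosome"]) - set(CHROMOSOMES))
        if bad:
            raise ValidationError(f"unknown chromosomes in manifest: {bad}")
        if (f["position"] < 0).any():
            raise ValidationError("negative probe positions in manifest")

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index


@dataclass
class MQTLCatalog:
    """Organ -> set of mQTL probe ids (organ-specific methylation loci)."""

    organ_probes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        bad = sorted(set(self.organ_probes) - set(CLASSES))
        if bad:
            raise ValidationError(f"catalog organs outside the class vocabulary: {bad}")
        empty = sorted(o for o, p in self.organ_probes.items() if not p)
        if empty:
            raise ValidationError(f"catalog organs with empty probe sets: {empty}")

    @property
    def union_probes(self) -> frozenset[str]:
        out: set[str] = set()
        for probes in self.organ_probes.values():
            out |= probes
        return frozenset(out)

    def union_for(self, organs: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for o in organs:
            if o not in self.organ_probes:
                raise ValidationError(f"organ {o!r} not present in mQTL catalog")
            out |= self.organ_probes[o]
        return frozenset(out)


@dataclass
class TrainedClassifier:
    """A trained feed-forward classifier plus everything inference needs.

    ``weights`` holds float32 ``(W, b)`` pairs per fully connected layer,
    W of shape (in_dim, out_dim). ``preprocessing_state`` carries the
    per-probe imputation means frozen at training time (beta scale).
    """

    layer_dims: list[int]
    dropout_rate: float
    weights: list[tuple[np.ndarray, np.ndarray]]
    class_order: list[str]
    selected_probes: list[str]
    preprocessing_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.selected_probes) != self.layer_dims[0]:
            raise ValidationError(
                f"{len(self.selected_probes)} selected probes but input layer "
                f"has {self.layer_dims[0]} nodes"
            )
        if self.layer_dims[-1] != len(self.class_order):
            raise ValidationError(
                f"output layer has {self.layer_dims[-1]} nodes for "
                f"{len(self.class_order)} classes"
            )
        if len(self.weights) != len(self.layer_dims) - 1:
            raise ValidationError("weight list length does not match layer_dims")
        for li, (w, b) in enumerate(self.weights):
            expect = (self.layer_dims[li], self.layer_dims[li + 1])
            if w.shape != expect or b.shape != (expect[1],):
                raise ValidationError(f"layer {li} weight shape {w.shape} != {expect}")


@dataclass
class PredictionReport:
    """Per-sample class probabilities and derived calls."""

    frame: pd.DataFrame  # sample_id, p_<class>..., predicted_label, second_label, confidence
    class_order: list[str]

    def __post_init__(self) -> None:
        prob_cols = [f"p_{c}" for c in self.class_order]
        p = self.frame[prob_cols].to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("probability rows do not sum to 1 within 1e-6")

    @property
    def probabilities(self) -> np.ndarray:
        return self.frame[[f"p_{c}" for c in self.class_order]].to_numpy()

    @property
    def predicted_labels(self) -> list[str]:
        return list(self.frame["predicted_label"])


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def load_beta_matrix(path: str | Path, orientation: str = "probes-by-samples") -> BetaMatrix:
    """Load a beta matrix, normalizing orientation to probes x samples.

    ``orientation`` is explicit ("probes-by-samples" or "samples-by-probes");
    no auto-detection is attempted because silent transposition of a large
    matrix is unrecoverable downstream.
    """
    path = Path(path)
    if orientation not in {"probes-by-samples", "samples-by-probes"}:
        raise ValidationError(f"unknown orientation {orientation!r}")
    # pandas mangles duplicate header names, so check them on the raw line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    _check_unique(header, "column ids in header")
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=list(_NA_TOKENS),
        keep_default_na=False, dtype=str,
    )
    values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=np.float64)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "samples-by-probes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return BetaMatrix(row_ids, col_ids, values)


def save_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    path = Path(path)
    bm.to_frame().to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="probe_id")


def load_cohort_metadata(path: str | Path) -> SampleSheet:
    """Load a sample sheet CSV; a missing ``label`` column marks the sheet
    inference-only rather than failing."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "batch", "is_metastasis"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    labels = list(df["label"]) if "label" in df.columns else None
    mets = [s.strip().lower() in {"true", "1", "yes"} for s in df["is_metastasis"]]
    return SampleSheet(list(df["sample_id"]), labels, list(df["batch"]), mets)


def save_cohort_metadata(sheet: SampleSheet, path: str | Path) -> None:
    cols = {"sample_id": sheet.sample_ids}
    if sheet.labels is not None:
        cols["label"] = sheet.labels
    cols["batch"] = sheet.batches
    cols["is_metastasis"] = sheet.is_metastasis
    pd.DataFrame(cols).to_csv(Path(path), index=False)


def load_probe_annotations(
    manifest_path: str | Path, catalog_path: str | Path
) -> tuple[ProbeAnnotations, MQTLCatalog]:
    """Load the array manifest and the long-format mQTL catalog together.

    Catalog organs outside the six-class vocabulary are dropped with a
    warning (the source catalogs describe more organs than the classifier
    uses); catalog probes absent from the manifest are counted and warned
    about but kept — public catalogs routinely exceed array content.
    """
    mf = pd.read_csv(Path(manifest_path))
    need = {"probe_id", "chromosome", "position", "snp_overlap"}
    if not need <= set(mf.columns):
        raise ValidationError(f"manifest missing columns: {sorted(need - set(mf.columns))}")
    mf["snp_overlap"] = mf["snp_overlap"].astype(str).str.lower().isin(["true", "1", "yes"])
    ann = ProbeAnnotations(
        mf.set_index("probe_id")[["chromosome", "position", "snp_overlap"]]
    )

    cat = pd.read_csv(Path(catalog_path))
    if not {"organ", "probe_id"} <= set(cat.columns):
        raise ValidationError("mQTL catalog must have columns organ,probe_id")
    rejected = sorted(set(cat["organ"]) - set(CLASSES))
    if rejected:
        warnings.warn(
            f"mQTL catalog organs outside the {len(CLASSES)}-class vocabulary "
            f"rejected: {rejected}", stacklevel=2,
        )
        cat = cat[cat["organ"].isin(CLASSES)]
    organ_probes = {
        organ: frozenset(group["probe_id"].astype(str))
        for organ, group in cat.groupby("organ")
    }
    catalog = MQTLCatalog(organ_probes)
    unknown = catalog.union_probes - set(ann.probe_ids.astype(str))
    if unknown:
        warnings.warn(
            f"{len(unknown)} mQTL catalog probes are absent from the manifest",
            stacklevel=2,
        )
    return ann, catalog


def save_mqtl_catalog(catalog: MQTLCatalog, path: str | Path) -> None:
    rows = [
        {"organ": organ, "probe_id": probe}
        for organ in sorted(catalog.organ_probes)
        for probe in sorted(catalog.organ_probes[organ])
    ]
    pd.DataFrame(rows, columns=["organ", "probe_id"]).to_csv(Path(path), index=False)


def save_probe_annotations(ann: ProbeAnnotations, path: str | Path) -> None:
    ann.frame.to_csv(Path(path), index_label="probe_id")


# --- model persistence ------------------------------------------------------

def save_model(model: TrainedClassifier, directory: str | Path) -> None:
    """Persist a model as a JSON manifest + raw little-endian float32 arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "layer_dims": model.layer_dims,
        "dropout_rate": model.dropout_rate,
        "class_order": model.class_order,
        "preprocessing_state": {
            k: (list(map(float, v)) if isinstance(v, (list, np.ndarray)) else v)
            for k, v in model.preprocessing_state.items()
        },
        "weight_files": [],
    }
    for li, (w, b) in enumerate(model.weights):
        wf, bf = f"layer{li}_W.f32", f"layer{li}_b.f32"
        np.ascontiguousarray(w, dtype="<f4").tofile(directory / wf)
        np.ascontiguousarray(b, dtype="<f4").tofile(directory / bf)
        manifest["weight_files"].append(
            {"W": wf, "b": bf, "shape": list(w.shape)}
        )
    (directory / "model.json").write_text(json.dumps(manifest, indent=1))
    (directory / "selected_probes.txt").write_text(
        "\n".join(model.selected_probes) + "\n"
    )


def load_model(directory: str | Path) -> TrainedClassifier:
    directory = Path(directory)
    manifest_path = directory / "model.json"
    if not manifest_path.exists():
        raise ValidationError(f"missing model manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    probes_path = directory / "selected_probes.txt"
    if not probes_path.exists():
        raise ValidationError(f"missing probe list {probes_path}")
    selected = probes_path.read_text().splitlines()
    weights: list[tuple[np.ndarray, np.ndarray]] = []
    for entry in manifest["weight_files"]:
        shape = tuple(entry["shape"])
        for key, expect in (("W", shape), ("b", (shape[1],))):
            f = directory / entry[key]
            if not f.exists():
                raise ValidationError(f"missing or corrupt weight file {f}")
        w = np.fromfile(directory / entry["W"], dtype="<f4")
        b = np.fromfile(directory / entry["b"], dtype="<f4")
        if w.size != shape[0] * shape[1] or b.size != shape[1]:
            raise ValidationError(f"corrupt weight file for layer shape {shape}")
        weights.append((w.reshape(shape), b))
    state = manifest.get("preprocessing_state", {})
    if "impute_means" in state:
        state["impute_means"] = np.asarray(state["impute_means"], dtype=np.float64)
    return TrainedClassifier(
        layer_dims=list(manifest["layer_dims"]),
        dropout_rate=float(manifest["dropout_rate"]),
        weights=weights,
        class_order=list(manifest["class_order"]),
        selected_probes=selected,
        preprocessing_state=state,
    )


def save_prediction_report(report: PredictionReport, path: str | Path) -> None:
    report.frame.to_csv(Path(path), index=False)
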