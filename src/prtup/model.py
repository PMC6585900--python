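"""RBF-kernel SVM training, hyperparameter grid search and deployment.

The classifier is a libsvm-backed SVC with sigmoid probability calibration.
A :class:`TrainedModel` archive bundles everything needed to score new
peptides — encoding configuration, property table, selected feature indices
and the fitted SVM — so predictions are a pure function of the archive and
the input sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoding import EncodingConfig, PropertyTable, encode
from .peptides import Peptide

ARCHIVE_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters and the decision threshold tp.

    ``tp`` is applied to the calibrated positive-class probability; a
    probability exactly equal to tp is classified positive.
    """

    C: float = 1.0
    gamma: float = 0.125
    probability: bool = True
    tp: float = 0.5

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ModelError("C and gamma must be positive")
        if not (0 < self.tp < 1):
            raise ModelError("tp must lie strictly between 0 and 1")

    def to_dict(self) -> dict:
        return {"C": self.C, "gamma": self.gamma, "probability": self.probability, "tp": self.tp}

    @classmethod
    def from_dict(cls, d: dict) -> "SVMConfig":
        return cls(**d)


def default_C_grid() -> np.ndarray:
    """log2-spaced penalty grid 2^-5 .. 2^15, exponent step 2 (11 points)."""
    return 2.0 ** np.arange(-5, 16, 2)


def default_gamma_grid() -> np.ndarray:
    """log2-spaced kernel-width grid 2^-15 .. 2^3, exponent step 2 (10 points)."""
    return 2.0 ** np.arange(-15, 4, 2)


def grid_search(
    matrix: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 10,
    C_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[SVMConfig, pd.DataFrame]:
    """Exhaustive (C, gamma) search by seeded stratified CV accuracy.

    Ties break toward smaller C, then smaller gamma. Returns the winning
    config plus the full accuracy surface for logging.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ModelError("grid search needs samples from both classes")
    C_grid = np.sort(np.asarray(C_grid if C_grid is not None else default_C_grid(), dtype=float))
    gamma_grid = np.sort(
        np.asarray(gamma_grid if gamma_grid is not None else default_gamma_grid(), dtype=float)
    )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    best = (-1.0, None, None)
    for C in C_grid:
        for gamma in gamma_grid:
            correct = 0
            for tr, te in folds:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                correct += int((clf.predict(X[te]) == y[te]).sum())
            acc = correct / len(y)
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            if acc > best[0]:  # strict: first (smallest C, gamma) max wins
                best = (acc, C, gamma)
    surface = pd.DataFrame(rows)
    return SVMConfig(C=best[1], gamma=best[2]), surface


def train_svm(
    matrix: np.ndarray, labels: np.ndarray, config: SVMConfig, seed: int = 0
) -> SVC:
    """Fit the RBF SVM (with probability calibration when configured)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ModelError("training needs samples from both classes")
    clf = SVC(
        C=config.C,
        gamma=config.gamma,
        kernel="rbf",
        probability=config.probability,
        random_state=seed,
    )
    clf.fit(np.asarray(matrix, dtype=float), y)
    return clf


@dataclass
class TrainedModel:
    """Self-contained deployable predictor.

    Predictions depend only on the archived state: the encoder settings,
    the embedded property table, the selected-feature mask and the fitted
    SVM. ``provenance`` records seeds and dataset fingerprints.
    """

    encoding_config: EncodingConfig
    property_table: PropertyTable
    selected_features: np.ndarray
    svm: SVC
    svm_config: SVMConfig
    provenance: dict = field(default_factory=dict)

    @property
    def min_length(self) -> int:
        """Shortest peptide this model can encode."""
        if self.encoding_config.mode == "dipeptide":
            return 2
        return max(3, self.encoding_config.lam + 1)

    def _encode_batch(self, peptides: Sequence[Peptide]) -> np.ndarray:
        rows = [
            encode(p, self.encoding_config, self.property_table) for p in peptides
        ]
        return np.vstack(rows)[:, self.selected_features]

    def predict_proba(self, peptides: Sequence[Peptide]) -> np.ndarray:
        """Calibrated positive-class probability per peptide."""
        X = self._encode_batch(peptides)
        pos_col = int(np.where(self.svm.classes_ == 1)[0][0])
        return self.svm.predict_proba(X)[:, pos_col]

    def predict(
        self,
        peptides: Iterable[Peptide | tuple[str, str]],
        tp: float | None = None,
        batch_size: int = 1000,
    ) -> Iterator[dict]:
        """Stream predictions in input order, one dict per record.

        Memory is bounded by ``batch_size``, not input size. Items that are
        ``(record_id, error)`` tuples (from lenient FASTA streaming) or
        peptides too short for the model's lambda yield an error row with
        ``probability`` and ``label`` set to None; the stream continues.
        """
        threshold = self.svm_config.tp if tp is None else tp
        batch: list[Peptide] = []

        def flush() -> Iterator[dict]:
            if not batch:
                return
            probs = self.predict_proba(batch)
            for p, prob in zip(batch, probs):
                yield {
                    "id": p.id,
                    "sequence": p.sequence,
                    "probability": float(prob),
                    "label": "positive" if prob >= threshold else "negative",
                    "error": "",
                }
            batch.clear()

        for item in peptides:
            if isinstance(item, tuple):
                yield from flush()
                yield {"id": item[0], "sequence": "", "probability": None,
                       "label": None, "error": item[1]}
                continue
            if len(item) < self.min_length:
                yield from flush()
                yield {"id": item.id, "sequence": item.sequence, "probability": None,
                       "label": None,
                       "error": f"length {len(item)} < required {self.min_length}"}
                continue
            batch.append(item)
            if len(batch) >= batch_size:
                yield from flush()
        yield from flush()

    def with_threshold(self, tp: float) -> "TrainedModel":
        return replace(self, svm_config=replace(self.svm_config, tp=tp))

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": ARCHIVE_FORMAT_VERSION,
                "encoding_config": self.encoding_config.to_dict(),
                "property_table": self.property_table.to_dict(),
                "selected_features": np.asarray(self.selected_features),
                "svm": self.svm,
                "svm_config": self.svm_config.to_dict(),
                "provenance": self.provenance,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = joblib.load(path)
        if d.get("format_version") != ARCHIVE_FORMAT_VERSION:
            raise ModelError(f"unsupported archive version {d.get('format_version')}")
        return cls(
            encoding_config=EncodingConfig.from_dict(d["encoding_config"]),
            property_table=PropertyTable.from_dict(d["property_table"]),
            selected_features=np.asarray(d["selected_features"]),
            svm=d["svm"],
            svm_config=SVMConfig.from_dict(d["svm_config"]),
            provenance=d["provenance"],
        )


def build_model(
    matrix: np.ndarray,
    labels: np.ndarray,
    encoding_config: EncodingConfig,
    property_table: PropertyTable,
    selected_features: np.ndarray,
    svm_config: SVMConfig,
    seed: int = 0,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit the SVM on the selected columns and assemble the archive."""
    selected = np.asarray(selected_features)
    svm = train_svm(np.asarray(matrix)[:, selected], labels, svm_config, seed=seed)
    return TrainedModel(
        encoding_config=encoding_config,
        property_table=property_table,
        selected_features=selected,
        svm=svm,
        svm_config=svm_config,
        provenance={"seed": seed, **(provenance or {})},
    )
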