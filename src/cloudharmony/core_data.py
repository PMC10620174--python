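"""Lesion-level feature tables: data model, I/O, standardization, PCA, splitting.

The exchange object throughout the package is the :class:`LesionTable` — one
row per lesion, identified by ``lesion_id``, grouped into patients
(``patient_id``) that are nested in acquisition centers (``center``), each
lesion imaged on one scanner (``scanner``), plus ``d`` continuous radiomic
features named ``f1..fd``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("cloudharmony")

ID_COLUMNS = ["lesion_id", "patient_id", "center", "scanner"]

#: floor applied to a zero per-feature standard deviation so that degenerate
#: (constant) features standardize to zero instead of raising
SD_FLOOR = 1e-8


class FormatError(ValueError):
    """A table file does not have the expected columns or dtypes."""


class ConsistencyError(ValueError):
    """A table violates a structural invariant (duplicate ids, split patients...)."""


def _feature_columns(d: int) -> list[str]:
    return [f"f{i}" for i in range(1, d + 1)]


@dataclass
class LesionTable:
    """One row per lesion: ids, center/scanner labels and d features.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain ``lesion_id, patient_id, center, scanner, f1..fd``.
        Validated on construction; a defensive copy is taken.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        feat_cols = [c for c in df.columns if c not in ID_COLUMNS]
        d = len(feat_cols)
        if d == 0:
            raise FormatError("table has no feature columns")
        expected = _feature_columns(d)
        if feat_cols != expected:
            raise FormatError(
                f"feature columns must be named f1..f{d} in order, got {feat_cols[:5]}..."
            )
        df = df.copy()
        for c in ID_COLUMNS:
            df[c] = df[c].astype(str)
        try:
            df[feat_cols] = df[feat_cols].astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric feature value: {exc}") from exc
        if df[feat_cols].isna().any().any() or not np.isfinite(df[feat_cols].to_numpy()).all():
            raise ConsistencyError("features contain missing or non-finite values")
        if df["lesion_id"].duplicated().any():
            dup = df.loc[df["lesion_id"].duplicated(), "lesion_id"].iloc[0]
            raise ConsistencyError(f"duplicate lesion_id {dup!r}")
        centers_per_patient = df.groupby("patient_id")["center"].nunique()
        if (centers_per_patient > 1).any():
            bad = centers_per_patient[centers_per_patient > 1].index[0]
            raise ConsistencyError(f"patient {bad!r} appears with more than one center")
        self.df = df.reset_index(drop=True)

    # -- accessors -----------------------------------------------------------

    @property
    def d(self) -> int:
        return self.df.shape[1] - len(ID_COLUMNS)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def feature_columns(self) -> list[str]:
        return _feature_columns(self.d)

    @property
    def features(self) -> np.ndarray:
        """n x d float matrix (a copy)."""
        return self.df[self.feature_columns].to_numpy(float)

    @property
    def lesion_ids(self) -> np.ndarray:
        return self.df["lesion_id"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].to_numpy()

    def with_features(self, matrix: np.ndarray, columns: list[str] | None = None) -> "LesionTable":
        """Return a new table with identical id columns and replaced features."""
        matrix = np.asarray(matrix, float)
        if matrix.shape[0] != self.n:
            raise ConsistencyError(
                f"feature matrix has {matrix.shape[0]} rows for a table of {self.n}"
            )
        cols = columns if columns is not None else _feature_columns(matrix.shape[1])
        out = self.df[ID_COLUMNS].copy()
        out[cols] = matrix
        # rename to the canonical f1..fd schema regardless of supplied names
        out.columns = ID_COLUMNS + _feature_columns(matrix.shape[1])
        return LesionTable(out)

    def subset(self, mask) -> "LesionTable":
        return LesionTable(self.df.loc[mask].reset_index(drop=True))

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")

    def __eq__(self, other) -> bool:  # value semantics for tests
        if not isinstance(other, LesionTable):
            return NotImplemented
        return self.df.equals(other.df)


def read_lesion_table(path) -> LesionTable:
    """Read and validate a lesion table CSV (lesion_id,patient_id,center,scanner,f1..fd)."""
    try:
        df = pd.read_csv(path, dtype={c: str for c in ID_COLUMNS}, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return LesionTable(df)


@dataclass
class SurvivalTable:
    """Patient-level right-censored outcomes: patient_id, time > 0, event in {0,1}."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for c in ("patient_id", "time", "event"):
            if c not in df.columns:
                raise FormatError(f"survival table missing column {c!r}")
        df = df.copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        if df["patient_id"].duplicated().any():
            raise ConsistencyError("duplicate patient_id in survival table")
        if (df["time"] <= 0).any():
            raise ConsistencyError("survival times must be positive")
        if not df["event"].isin((0, 1)).all():
            raise ConsistencyError("event must be 0 or 1")
        self.df = df.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")

    def subset(self, patient_ids) -> "SurvivalTable":
        keep = self.df["patient_id"].isin(set(map(str, patient_ids)))
        return SurvivalTable(self.df.loc[keep].reset_index(drop=True))


def read_survival_table(path) -> SurvivalTable:
    try:
        df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return SurvivalTable(df)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-feature z-score parameters, fitted on a training subset only."""

    mean: np.ndarray
    sd: np.ndarray
    floored: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def inverse(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, float) * self.sd + self.mean


def standardize(
    table: LesionTable, params: StandardizationParams | None = None
) -> tuple[LesionTable, StandardizationParams]:
    """Z-score each feature; fit mean/sd on ``table`` when params are absent.

    Zero-variance features get their sd floored at ``SD_FLOOR`` with a logged
    warning, so constant columns standardize to exactly zero rather than NaN.
    """
    x = table.features
    if params is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        floored = sd < SD_FLOOR
        if floored.any():
            cols = [table.feature_columns[i] for i in np.flatnonzero(floored)]
            logger.warning("constant feature(s) %s: sd floored at %g", cols, SD_FLOOR)
            warnings.warn(f"constant feature(s) {cols}: sd floored at {SD_FLOOR}")
            sd = np.where(floored, SD_FLOOR, sd)
        params = StandardizationParams(mean=mean, sd=sd, floored=floored)
    z = (x - params.mean) / params.sd
    return table.with_features(z), params


def unstandardize(table: LesionTable, params: StandardizationParams) -> LesionTable:
    return table.with_features(params.inverse(table.features))


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def pca_reduce(
    matrix: np.ndarray, n_components: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Project rows onto the leading principal components.

    Feature tables that are not already embeddings are reduced to 16
    components before survival modeling, the same dimensionality as the
    autoencoder bottleneck.

    Returns
    -------
    scores : (n, n_components) array, components ordered by decreasing variance
    explained : explained-variance fractions of the kept components
    """
    matrix = np.asarray(matrix, float)
    n, d = matrix.shape
    if n_components > min(n, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, d)=min({n}, {d})"
        )
    if n <= n_components:
        raise ValueError(f"need n > n_components, got n={n}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    return scores, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------

def split_by_patient(
    table: LesionTable,
    survival: SurvivalTable | None,
    fraction: float,
    seed: int,
) -> tuple[tuple[LesionTable, SurvivalTable | None], tuple[LesionTable, SurvivalTable | None]]:
    """Partition patients (not lesions) into train/test at the given fraction.

    All lesions of a patient land on one side. Deterministic given the seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    patients = np.unique(table.patient_ids)
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_set = set(patients[order[:n_train]])
    in_train = np.array([p in train_set for p in table.patient_ids])
    train_tab, test_tab = table.subset(in_train), table.subset(~in_train)
    if survival is None:
        return (train_tab, None), (test_tab, None)
    return (
        (train_tab, survival.subset(train_tab.patient_ids)),
        (test_tab, survival.subset(test_tab.patient_ids)),
    )
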