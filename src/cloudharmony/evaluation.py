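"""Evaluation procedures: confounder predictability, patient representations,
and repeated-split survival concordance.

Experiment 1 — deconfusion power: bootstrap logistic regression predicting a
confounder (center or scanner) from lesion features; per trial the model is
fitted on a with-replacement resample and scored on the out-of-bag lesions.
Modalities are compared with two-sided paired t-tests on the per-trial
accuracies.

Experiment 3 — prognostic power: each patient's lesion cloud is summarized as
a centroid, four cloud-topology indexes (mean/sd of pairwise inter-lesion
distances, mean/sd of lesion-to-centroid distances), or their concatenation;
the representation feeds a ridge-stabilized Cox proportional-hazards model
over repeated patient-level train/test splits, scored by Harrell's
concordance index, with one-sided paired t-tests between modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .core_data import SurvivalTable, pca_reduce

REPRESENTATION_KINDS = ("centroid", "cloud-description", "combined")


# ---------------------------------------------------------------------------
# Experiment 1: confounder predictability
# ---------------------------------------------------------------------------

@dataclass
class AccuracyDistribution:
    """Per-trial out-of-bag accuracies of the confounder classifier."""

    modality: str
    factor: str
    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    def __str__(self) -> str:
        return f"{self.modality}/{self.factor}: {self.mean:.4f} ± {self.sd:.4f}"


def confounder_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    n_trials: int = 100,
    seed: int = 0,
    modality: str = "",
    factor: str = "",
) -> AccuracyDistribution:
    """Bootstrap logistic-regression accuracy for predicting a confounder.

    Per trial: a with-replacement resample of the rows is the training set;
    accuracy is measured on the out-of-bag rows. The classifier is
    L2-penalized (multinomial) logistic regression with the fixed default
    penalty. A resample missing a class is redrawn (at most 10 attempts).
    """
    x = np.asarray(features, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 5:
        raise ValueError("every class needs >= 5 samples")
    n = len(labels)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_trials)
    for t in range(n_trials):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if len(np.unique(labels[idx])) == len(classes) and oob.size > 0:
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample containing all classes")
        clf = LogisticRegression(C=1.0, max_iter=500)
        clf.fit(x[idx], labels[idx])
        accs[t] = float(np.mean(clf.predict(x[oob]) == labels[oob]))
    return AccuracyDistribution(modality=modality, factor=factor, accuracies=accs)


def _paired_t(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0  # identical vectors: no evidence by convention
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.pvalue)


def paired_accuracy_test(
    a: AccuracyDistribution, b: AccuracyDistribution, alternative: str = "two-sided"
) -> float:
    """Paired t-test on per-trial accuracies (trials paired by shared resamples)."""
    return _paired_t(a.accuracies, b.accuracies, alternative)


# ---------------------------------------------------------------------------
# Patient representations
# ---------------------------------------------------------------------------

@dataclass
class RepresentationSet:
    """Per-patient vectors of one representation kind, row-aligned with
    ``patients``; single-lesion patients are flagged degenerate (their four
    cloud indexes are zeros)."""

    kind: str
    patients: list[str]
    matrix: np.ndarray
    degenerate: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cols = [f"r{i}" for i in range(1, self.matrix.shape[1] + 1)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "patient_id", self.patients)
        return df


def _cloud_indexes(points: np.ndarray) -> np.ndarray:
    """mean/sd of pairwise inter-lesion distances and of lesion-to-centroid
    distances (population sd); zeros for a single lesion."""
    k = points.shape[0]
    if k < 2:
        return np.zeros(4)
    diffs = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diffs**2).sum(-1))
    iu = np.triu_indices(k, 1)
    pair = dist[iu]
    centroid = points.mean(axis=0)
    to_c = np.linalg.norm(points - centroid, axis=1)
    return np.array([pair.mean(), pair.std(), to_c.mean(), to_c.std()])


def build_representation(
    patient_ids: np.ndarray, matrix: np.ndarray, kind: str
) -> RepresentationSet:
    """Summarize each patient's lesion cloud as a single vector.

    kind:
      * ``centroid`` — coordinate-wise mean profile of the patient's lesions;
      * ``cloud-description`` — the four Euclidean cloud-topology indexes;
      * ``combined`` — their concatenation.
    """
    if kind not in REPRESENTATION_KINDS:
        raise ValueError(f"unknown representation kind {kind!r}")
    matrix = np.asarray(matrix, float)
    patient_ids = np.asarray(patient_ids)
    if len(patient_ids) != matrix.shape[0]:
        raise ValueError("patient_ids and matrix rows must align")
    if len(patient_ids) == 0:
        raise ValueError("empty table")
    groups: dict[str, list[int]] = {}
    for i, p in enumerate(patient_ids):
        groups.setdefault(str(p), []).append(i)
    patients = sorted(groups)
    rows, degenerate = [], []
    for p in patients:
        pts = matrix[groups[p]]
        if pts.shape[0] < 2:
            degenerate.append(p)
        if kind == "centroid":
            rows.append(pts.mean(axis=0))
        elif kind == "cloud-description":
            rows.append(_cloud_indexes(pts))
        else:
            rows.append(np.concatenate([pts.mean(axis=0), _cloud_indexes(pts)]))
    return RepresentationSet(
        kind=kind, patients=patients, matrix=np.vstack(rows), degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# Experiment 3: repeated-split Cox concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Harrell's C per split, on train and test patients."""

    modality: str
    kind: str
    train_ci: np.ndarray
    test_ci: np.ndarray
    n_failed: int = 0

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_ci))

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_ci))


def _fit_cox(df: pd.DataFrame, penalizer: float) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def prognostic_eval(
    representations: RepresentationSet,
    survival: SurvivalTable,
    n_splits: int = 20,
    split_fraction: float = 0.7,
    seed: int = 0,
    penalizer: float = 1e-4,
    modality: str = "",
) -> ConcordanceReport:
    """Cox proportional-hazards concordance over repeated patient splits.

    Splits are a deterministic function of (patient set, seed), so reports
    computed for different modalities with the same seed are paired split by
    split. Non-converging fits escalate the ridge penalty tenfold up to three
    times before the split is recorded as failed.
    """
    rep_df = representations.frame()
    surv_df = survival.df
    df = rep_df.merge(surv_df, on="patient_id", how="inner")
    if len(df) < len(rep_df):
        missing = set(rep_df["patient_id"]) - set(surv_df["patient_id"])
        raise ValueError(f"survival records missing for patients {sorted(missing)[:5]}")
    feat_cols = [c for c in df.columns if c.startswith("r")]
    # drop constant columns (e.g. all-degenerate cloud indexes): Cox cannot use them
    keep = [c for c in feat_cols if df[c].nunique() > 1]
    patients = df["patient_id"].to_numpy()
    n_pat = len(patients)
    if n_pat < 10:
        raise ValueError("need >= 10 patients for split evaluation")

    train_ci, test_ci, n_failed = [], [], 0
    for split in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, split]))
        order = rng.permutation(n_pat)
        n_train = int(round(split_fraction * n_pat))
        tr, te = order[:n_train], order[n_train:]
        cols = keep + ["time", "event"]
        df_tr, df_te = df.iloc[tr][cols], df.iloc[te][cols]
        pen = penalizer
        cph = None
        for _ in range(4):
            try:
                cph = _fit_cox(df_tr, pen)
                break
            except (ConvergenceError, np.linalg.LinAlgError):
                pen *= 10.0
        if cph is None:
            n_failed += 1
            continue
        for part, out in ((df_tr, train_ci), (df_te, test_ci)):
            risk = cph.predict_partial_hazard(part).to_numpy()
            out.append(concordance_index(part["time"], -risk, part["event"]))
    return ConcordanceReport(
        modality=modality,
        kind=representations.kind,
        train_ci=np.asarray(train_ci),
        test_ci=np.asarray(test_ci),
        n_failed=n_failed,
    )


def paired_concordance_test(
    a: ConcordanceReport,
    b: ConcordanceReport,
    alternative: str = "greater",
    phase: str = "test",
) -> float:
    """One-sided (default) paired t-test on per-split concordances:
    alternative='greater' asks whether a outperforms b."""
    va = a.test_ci if phase == "test" else a.train_ci
    vb = b.test_ci if phase == "test" else b.train_ci
    return _paired_t(va, vb, alternative)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def experiment_report(
    modalities: dict[str, np.ndarray],
    ids: pd.DataFrame,
    survival: SurvivalTable | None,
    baseline: str = "radiomics",
    reference: str = "dual_adae",
    embedding_modalities: tuple[str, ...] = ("dual_adae",),
    factors: tuple[str, ...] = ("center", "scanner"),
    n_trials: int = 100,
    n_splits: int = 20,
    split_fraction: float = 0.7,
    pca_components: int = 16,
    seed: int = 0,
) -> dict:
    """Run Experiments 1 and 3 over named, row-aligned feature sets.

    ``modalities`` maps a name to an (n_lesions, m) matrix aligned row-wise
    with ``ids`` (columns lesion_id, patient_id, center, scanner). Modalities
    not listed as embeddings are PCA-reduced to ``pca_components`` before the
    survival models. Returns accuracy and concordance tables plus the raw
    per-trial distributions.
    """
    n = len(ids)
    for name, mat in modalities.items():
        if np.asarray(mat).shape[0] != n:
            raise ValueError(f"modality {name!r} is not row-aligned with ids ({n} rows)")
    if baseline not in modalities:
        raise ValueError(f"baseline modality {baseline!r} missing")

    # -- Experiment 1 -------------------------------------------------------
    acc: dict[tuple[str, str], AccuracyDistribution] = {}
    for factor in factors:
        labels = ids[factor].to_numpy()
        for name, mat in modalities.items():
            acc[(name, factor)] = confounder_accuracy(
                mat, labels, n_trials=n_trials, seed=seed, modality=name, factor=factor
            )
    rows = []
    for name in modalities:
        row: dict = {"modality": name}
        for factor in factors:
            a = acc[(name, factor)]
            base = acc[(baseline, factor)]
            p = 1.0 if name == baseline else paired_accuracy_test(a, base, "two-sided")
            row[f"{factor}_mean"] = a.mean
            row[f"{factor}_sd"] = a.sd
            row[f"{factor}_p_vs_{baseline}"] = p
            row[f"{factor}_significant"] = bool(p < 1e-3 and a.mean < base.mean)
        rows.append(row)
    accuracy_table = pd.DataFrame(rows)

    out = {"accuracy_table": accuracy_table, "accuracy_distributions": acc}
    if survival is None:
        return out

    # -- Experiment 3 -------------------------------------------------------
    reports: dict[tuple[str, str], ConcordanceReport] = {}
    patient_ids = ids["patient_id"].to_numpy()
    for name, mat in modalities.items():
        mat = np.asarray(mat, float)
        if name not in embedding_modalities and mat.shape[1] > pca_components:
            mat, _ = pca_reduce(mat, pca_components)
        for kind in REPRESENTATION_KINDS:
            reps = build_representation(patient_ids, mat, kind)
            reports[(name, kind)] = prognostic_eval(
                reps,
                survival,
                n_splits=n_splits,
                split_fraction=split_fraction,
                seed=seed,
                modality=name,
            )
    rows = []
    for name in modalities:
        row = {"modality": name}
        for kind in REPRESENTATION_KINDS:
            rep = reports[(name, kind)]
            row[f"{kind}_train_mean"] = rep.mean_train
            row[f"{kind}_test_mean"] = rep.mean_test
            if name != reference and reference in modalities:
                ref = reports[(reference, kind)]
                row[f"{kind}_p_train"] = paired_concordance_test(ref, rep, "greater", "train")
                row[f"{kind}_p_test"] = paired_concordance_test(ref, rep, "greater", "test")
        rows.append(row)
    out["concordance_table"] = pd.DataFrame(rows)
    out["concordance_reports"] = reports
    return out
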