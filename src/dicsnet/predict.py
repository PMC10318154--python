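"""Feature assembly and behavioral-score prediction.

Predictors are the coherent-source amplitudes and the significant TPDC edge
strengths from every frequency band.  Prediction uses a polynomial-kernel
support vector machine with an integer grid search over degree and cost in
[1, 10] and a fixed kernel coefficient (gamma = 0.25), evaluated over five
repeated stratified 75/25 train/test splits (a standard five-fold scheme is
available).  Features are standardized on the training split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("CELF", "WRDC", "VOC", "MORPH", "SEN", "EFFIC", "RCOMP")
AGE_COLUMNS = ("age_first_ci", "age_bilateral_ci", "age_ha_fit")


def validate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Check a behavioral-score table (one row per subject).

    Required columns: subject, group, the seven scores and three intervention
    ages.  Enforces the grouping rule: high-language (HL) subjects have CELF
    >= 100, low-language (LL) subjects CELF <= 85.
    """
    required = ["subject", "group", *SCORE_COLUMNS, *AGE_COLUMNS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"score table is missing columns: {missing}")
    hl = table[table.group == "HL"]
    if len(hl) and (hl.CELF < 100).any():
        raise ValueError("HL subjects must have CELF >= 100")
    ll = table[table.group == "LL"]
    if len(ll) and (ll.CELF > 85).any():
        raise ValueError("LL subjects must have CELF <= 85")
    return table


def read_scores_tsv(path) -> pd.DataFrame:
    return validate_scores(pd.read_csv(path, sep="\t"))


def write_scores_tsv(table: pd.DataFrame, path) -> None:
    validate_scores(table).to_csv(path, sep="\t", index=False)


@dataclass
class FeatureTable:
    """Subjects x features with provenance.

    values : (n_subjects, n_features), no missing entries (absent sources or
        edges are coded 0 and logged)
    """

    values: np.ndarray
    feature_labels: list
    subjects: list
    groups: list
    zero_filled: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_labels)) != len(self.feature_labels):
            raise ValueError("feature labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "subject", self.subjects)
        df.insert(1, "group", self.groups)
        return df


def assemble_features(source_sets: dict, graphs: dict,
                      bands: list | None = None,
                      groups: dict | None = None) -> FeatureTable:
    """Build the predictor table from per-subject source sets and graphs.

    Parameters
    ----------
    source_sets : {subject_id: {band_name: CoherentSourceSet}}
    graphs : {subject_id: {band_name: ConnectivityGraph}}

    Feature order is deterministic: for each band (input order), source
    amplitudes by rank, then edge strengths by (from, to) lexicographic over
    the union of edges seen in any subject.  Subjects missing a source rank
    or edge get 0 (recorded in ``zero_filled``).
    """
    subjects = list(source_sets.keys())
    if set(graphs.keys()) != set(subjects):
        missing = set(subjects) ^ set(graphs.keys())
        raise ValueError(f"subject mismatch between sources and graphs: "
                         f"{sorted(missing)}")
    if bands is None:
        bands = list(next(iter(source_sets.values())).keys())
    n_rank = {b: max((len(source_sets[s].get(b, [])) for s in subjects),
                     default=0) for b in bands}
    edge_keys = {b: sorted({(e.source, e.target)
                            for s in subjects
                            if b in graphs[s]
                            for e in graphs[s][b].edges})
                 for b in bands}
    labels = []
    for b in bands:
        labels += [f"{b}:S{r+1}:coh" for r in range(n_rank[b])]
        labels += [f"{b}:E{j}->{i}" for (j, i) in edge_keys[b]]
    values = np.zeros((len(subjects), len(labels)))
    zero_filled: dict = {}
    for si, s in enumerate(subjects):
        col = 0
        for b in bands:
            sset = source_sets[s].get(b)
            amps = sset.amplitudes() if sset is not None else np.zeros(0)
            for r in range(n_rank[b]):
                if r < amps.size:
                    values[si, col] = amps[r]
                else:
                    zero_filled.setdefault(s, []).append(labels[col])
                col += 1
            g = graphs[s].get(b)
            strengths = {(e.source, e.target): e.strength
                         for e in (g.edges if g is not None else [])}
            for key in edge_keys[b]:
                if key in strengths:
                    values[si, col] = strengths[key]
                else:
                    zero_filled.setdefault(s, []).append(labels[col])
                col += 1
    if zero_filled:
        logger.info("zero-filled %d absent source/edge features across %d "
                    "subjects", sum(len(v) for v in zero_filled.values()),
                    len(zero_filled))
    group_list = [groups.get(s, "") if groups else "" for s in subjects]
    return FeatureTable(values=values, feature_labels=labels,
                        subjects=subjects, groups=group_list,
                        zero_filled=zero_filled)


@dataclass
class PredictionReport:
    """Cross-validated prediction accuracy for one target."""

    target: str
    mode: str                    # 'classification' or 'regression'
    accuracy: float              # percent
    fold_accuracies: list        # percent per split
    hyperparameters: dict
    seed: int
    n_folds: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 100.0):
            raise ValueError("accuracy must be a percentage")

    def to_dict(self) -> dict:
        return {
            "target": self.target, "mode": self.mode,
            "accuracy_percent": self.accuracy,
            "fold_accuracies_percent": self.fold_accuracies,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed, "n_folds": self.n_folds,
        }


def svm_predict(
    features: np.ndarray,
    target: np.ndarray,
    mode: str = "classification",
    seed: int = 0,
    scheme: str = "repeated-75/25",
    n_splits: int = 5,
    gamma: float = 0.25,
    grid: range = range(1, 11),
    target_name: str = "target",
    inner_cv: int = 3,
) -> PredictionReport:
    """Polynomial-kernel SVM with grid search under cross-validation.

    Classification accuracy is the percentage of correct test labels.
    Regression "accuracy" is the percentage of test predictions within half a
    population standard deviation of the true score (a tolerance-band
    surrogate for continuous scores).  ``scheme`` is 'repeated-75/25'
    (five stratified 75/25 train/test splits) or 'kfold' (standard
    stratified five-fold).
    """
    from sklearn.model_selection import (GridSearchCV, KFold,
                                         StratifiedKFold,
                                         StratifiedShuffleSplit,
                                         ShuffleSplit)
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC, SVR

    X = np.asarray(features, float)
    y = np.asarray(target)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects")
    classify = mode == "classification"
    if classify:
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("need at least 2 subjects per class")
        if counts.min() < n_splits and scheme == "kfold":
            raise ValueError(
                f"class with {counts.min()} members cannot support "
                f"{n_splits} stratified folds")

    param_grid = {"svm__degree": list(grid), "svm__C": [float(c) for c in grid]}
    if classify:
        est = SVC(kernel="poly", gamma=gamma, coef0=1.0)
        splitter = (StratifiedShuffleSplit(n_splits=n_splits, test_size=0.25,
                                           random_state=seed)
                    if scheme == "repeated-75/25"
                    else StratifiedKFold(n_splits=n_splits, shuffle=True,
                                         random_state=seed))
    else:
        est = SVR(kernel="poly", gamma=gamma, coef0=1.0)
        splitter = (ShuffleSplit(n_splits=n_splits, test_size=0.25,
                                 random_state=seed)
                    if scheme == "repeated-75/25"
                    else KFold(n_splits=n_splits, shuffle=True,
                               random_state=seed))
    pipe = Pipeline([("scale", StandardScaler()), ("svm", est)])
    sd_pop = float(np.std(y)) if not classify else 0.0

    fold_acc = []
    chosen = []
    for tr, te in splitter.split(X, y if classify else np.zeros(len(y))):
        search = GridSearchCV(pipe, param_grid, cv=inner_cv,
                              scoring="accuracy" if classify
                              else "neg_mean_absolute_error", n_jobs=1)
        search.fit(X[tr], y[tr])
        pred = search.predict(X[te])
        if classify:
            acc = float(np.mean(pred == y[te]) * 100.0)
        else:
            acc = float(np.mean(np.abs(pred - y[te]) <= 0.5 * sd_pop) * 100.0)
        fold_acc.append(acc)
        chosen.append({k.replace("svm__", ""): v
                       for k, v in search.best_params_.items()})
    accuracy = float(np.mean(fold_acc))
    return PredictionReport(target=target_name,
                            mode="classification" if classify else "regression",
                            accuracy=accuracy, fold_accuracies=fold_acc,
                            hyperparameters={"gamma": gamma,
                                             "per_fold": chosen},
                            seed=seed, n_folds=n_splits)


def correlate_with_timing(features: pd.DataFrame,
                          ages: pd.DataFrame,
                          min_pairs: int = 5,
                          correct: bool = False) -> pd.DataFrame:
    """Pearson correlations of each feature with each intervention age.

    Rows with missing ages are dropped per pair; constant features yield
    ``r = NaN`` with a note.  No multiplicity correction by default
    (Bonferroni optional via ``correct=True``).
    """
    from scipy.stats import pearsonr

    feat_cols = [c for c in features.columns if c not in ("subject", "group")]
    age_cols = [c for c in ages.columns if c != "subject"]
    rows = []
    for fc in feat_cols:
        for ac in age_cols:
            x = np.asarray(features[fc], float)
            a = np.asarray(ages[ac], float)
            ok = np.isfinite(x) & np.isfinite(a)
            if ok.sum() < min_pairs:
                continue
            if np.std(x[ok]) == 0 or np.std(a[ok]) == 0:
                rows.append({"feature": fc, "covariate": ac, "n": int(ok.sum()),
                             "r": np.nan, "p": np.nan,
                             "note": "constant input"})
                continue
            r, pval = pearsonr(x[ok], a[ok])
            rows.append({"feature": fc, "covariate": ac, "n": int(ok.sum()),
                         "r": float(r), "p": float(pval), "note": ""})
    out = pd.DataFrame(rows)
    if correct and len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
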