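"""Four-class drug-resistance phenotype prediction and resistance scoring.

Mutations are labelled from the measured affinity fold change
(mutant / wild-type value of Kd, Ki or IC50, so >1 means weaker binding):
SRES (drop >= 5), RES (1.2 <= drop < 5), NEU (within the open +/-1.2-fold
band) and ISEN (increase >= 1.2-fold).  A random forest (1000 trees, 20
candidate features per split, unlimited depth) predicts per-class
confidences summing to 1.  The Resistance Score weights resistance-class
confidences against sensitivity-class ones with the per-class
cross-validation precisions:

    RS = S_SRES*P_SRES + S_RES*P_RES - S_NEU*P_NEU - S_ISEN*P_ISEN

and the normalised RS (NRS) min-max rescales RS within one scored
experiment so the top mutation maps to 1.0 and the bottom to 0.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .schema import FeatureSchema, FeatureVector, extract_pair_features, get_schema
from .sigcontext import AminoAcidMutation, SnvInContext
from .structmut import load_complex

CLASSES = ("SRES", "RES", "NEU", "ISEN")

SRES_FOLD = 5.0
NEU_BAND = 1.2

DEFAULT_RF_PARAMS = {"n_estimators": 1000, "max_features": 20,
                     "max_depth": None}


def label_from_fold_change(fold: float) -> str:
    """Phenotype label from a drop-oriented affinity fold change.

    ``fold`` > 1 is an affinity drop, < 1 a gain (1/fold-fold increase).
    The NEU band is open; the 1.2 boundaries are assigned outward to
    RES / ISEN.
    """
    if not fold > 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    if fold >= SRES_FOLD:
        return "SRES"
    if fold >= NEU_BAND:
        return "RES"
    if fold > 1.0 / NEU_BAND:
        return "NEU"
    return "ISEN"


@dataclass
class ClassScores:
    """Per-class confidences (sum to 1)."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.scores) != set(CLASSES):
            raise ValueError(f"scores must cover classes {CLASSES}")
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class confidences sum to {total}, not 1")
        if any(not 0 <= v <= 1 for v in self.scores.values()):
            raise ValueError("class confidences must lie in [0, 1]")

    @property
    def predicted_class(self) -> str:
        best = max(self.scores.values())
        for c in CLASSES:  # fixed order breaks exact ties
            if self.scores[c] == best:
                return c
        raise AssertionError

    @property
    def tied(self) -> bool:
        best = max(self.scores.values())
        return sum(1 for v in self.scores.values() if v == best) > 1


@dataclass
class ClassPrecisions:
    precisions: dict[str, float]

    def __post_init__(self) -> None:
        if any(not 0 <= v <= 1 for v in self.precisions.values()):
            raise ValueError("precisions must lie in [0, 1]")


@dataclass
class ResistanceResult:
    scores: ClassScores
    predicted_class: str
    rs: float
    nrs: float | None = None


@dataclass
class CVReport:
    auc: dict[str, float]
    precision: dict[str, float]
    recall: dict[str, float]
    mean_auc: float
    kappa: float
    confusion: np.ndarray
    k: int
    seed: int

    @property
    def class_precisions(self) -> ClassPrecisions:
        return ClassPrecisions(dict(self.precision))


@dataclass
class TrainingInstance:
    id: str
    mutation: str
    label: str
    fold_change: float
    features: FeatureVector


@dataclass
class TrainingSet:
    instances: list[TrainingInstance]
    schema: FeatureSchema
    report: dict = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return np.array([i.features.values for i in self.instances])

    @property
    def y(self) -> np.ndarray:
        return np.array([i.label for i in self.instances])


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    schema: FeatureSchema
    seed: int
    params: dict

    @property
    def classes(self) -> list[str]:
        return list(self.forest.classes_)


def parse_mutation_string(mut: str) -> tuple[str, int, str]:
    """Split a protein change like ``T790M`` into (ref, position, alt)."""
    ref, alt = mut[0], mut[-1]
    pos = int(mut[1:-1])
    return ref, pos, alt


def _placeholder_mutation(mut: str) -> AminoAcidMutation:
    ref, pos, alt = parse_mutation_string(mut)
    snv = SnvInContext(1, "A", "C", "N", "N")
    return AminoAcidMutation(pos, ref, alt, (snv,))


def build_training_set(
    table: str | Path | pd.DataFrame,
    schema: str | FeatureSchema = "aa-v1",
    seed: int = 0,
    cap: int = 180,
    offset: int = 0,
    chain: str | None = None,
) -> TrainingSet:
    """Assemble a labelled, feature-extracted training set.

    Expected columns: id, protein, mutation, n_mutations, wt_structure,
    mt_structure, affinity_wt, affinity_mt, measure, ligand_id.
    Multi-mutant rows are removed; labels come from the fold change
    ``affinity_mt / affinity_wt``; the over-represented SRES and RES
    classes are down-sampled uniformly at random (seeded) to ``cap``.
    The construction report logs every removal.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if isinstance(table, pd.DataFrame):
        df = table
        base = Path(".")
    else:
        df = pd.read_csv(table)
        base = Path(table).parent
    report = {"input_rows": len(df), "multi_mutant_removed": [],
              "unresolvable": [], "downsampled": {}}
    single = df[df["n_mutations"].astype(int) == 1]
    report["multi_mutant_removed"] = df.loc[
        df["n_mutations"].astype(int) > 1, "id"].astype(str).tolist()

    instances: list[TrainingInstance] = []
    wt_cache: dict[tuple[str, str], object] = {}
    for row in single.itertuples():
        fold = float(row.affinity_mt) / float(row.affinity_wt)
        label = label_from_fold_change(fold)
        try:
            wt_path = Path(row.wt_structure)
            mt_path = Path(row.mt_structure)
            if not wt_path.is_absolute():
                wt_path = base / wt_path
            if not mt_path.is_absolute():
                mt_path = base / mt_path
            key = (str(wt_path), row.ligand_id)
            if key not in wt_cache:
                wt_cache[key] = load_complex(wt_path, row.ligand_id)
            wt = wt_cache[key]
            mt = load_complex(mt_path, row.ligand_id)
            fv = extract_pair_features(
                wt, mt, _placeholder_mutation(row.mutation), schema,
                wt_affinity_nM=float(row.affinity_wt),
                measure=str(row.measure), chain=chain, offset=offset,
            )
        except (OSError, KeyError, ValueError) as exc:
            report["unresolvable"].append((str(row.id), str(exc)))
            continue
        instances.append(TrainingInstance(
            str(row.id), str(row.mutation), label, fold, fv))

    rng = np.random.default_rng(seed)
    kept: list[TrainingInstance] = []
    for cls in CLASSES:
        members = [i for i in instances if i.label == cls]
        if cls in ("SRES", "RES") and len(members) > cap:
            idx = rng.choice(len(members), size=cap, replace=False)
            report["downsampled"][cls] = len(members) - cap
            members = [members[j] for j in sorted(idx)]
        kept.extend(members)
    report["final_counts"] = {
        cls: sum(1 for i in kept if i.label == cls) for cls in CLASSES
    }
    return TrainingSet(kept, schema, report)


def train_classifier(
    ts: TrainingSet,
    params: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the random forest (1000 trees, 20 features/split, no depth cap)."""
    y = ts.y
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    p = dict(DEFAULT_RF_PARAMS)
    if params:
        p.update(params)
    p["max_features"] = min(p["max_features"], ts.X.shape[1])
    forest = RandomForestClassifier(random_state=seed, **p)
    forest.fit(ts.X, y)
    return ClassifierModel(forest, ts.schema, seed, p)


def _fit_predict_cv(
    X: np.ndarray, y: np.ndarray, k: int, seed: int, params: dict
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    present = [c for c in CLASSES if c in set(y)]
    min_count = min(np.sum(y == c) for c in present)
    if min_count < k:
        warnings.warn(
            f"smallest class has {min_count} members; reducing k from "
            f"{k} to {min_count}", stacklevel=3,
        )
        k = int(min_count)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    proba = np.zeros((len(y), len(present)))
    pred = np.empty(len(y), dtype=object)
    p = dict(params)
    p["max_features"] = min(p["max_features"], X.shape[1])
    for train_idx, test_idx in skf.split(X, y):
        forest = RandomForestClassifier(random_state=seed, **p)
        forest.fit(X[train_idx], y[train_idx])
        pp = forest.predict_proba(X[test_idx])
        cols = {c: j for j, c in enumerate(forest.classes_)}
        for ci, c in enumerate(present):
            if c in cols:
                proba[test_idx, ci] = pp[:, cols[c]]
        pred[test_idx] = forest.predict(X[test_idx])
    return proba, pred, present, k


def cross_validate(
    ts: TrainingSet,
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
) -> CVReport:
    """Stratified k-fold CV with one-vs-rest AUC, precision, recall, kappa.

    AUC is computed per class from pooled out-of-fold probabilities; the
    mean AUC is the unweighted class mean; kappa and the confusion matrix
    come from pooled out-of-fold hard predictions.
    """
    p = dict(DEFAULT_RF_PARAMS)
    if params:
        p.update(params)
    X, y = ts.X, ts.y
    proba, pred, present, k_used = _fit_predict_cv(X, y, k, seed, p)
    auc, prec, rec = {}, {}, {}
    for ci, c in enumerate(present):
        auc[c] = float(roc_auc_score((y == c).astype(int), proba[:, ci]))
        prec[c] = float(precision_score(y, pred, labels=[c], average="macro",
                                        zero_division=0))
        rec[c] = float(recall_score(y, pred, labels=[c], average="macro",
                                    zero_division=0))
    return CVReport(
        auc=auc, precision=prec, recall=rec,
        mean_auc=float(np.mean(list(auc.values()))),
        kappa=float(cohen_kappa_score(y, pred)),
        confusion=confusion_matrix(y, pred, labels=list(present)),
        k=k_used, seed=seed,
    )


def predict_scores(model: ClassifierModel, fv: FeatureVector) -> ClassScores:
    """Tree-vote class confidences for one feature vector."""
    if fv.schema.name != model.schema.name:
        raise ValueError(
            f"feature schema {fv.schema.name} does not match model schema "
            f"{model.schema.name}"
        )
    pp = model.forest.predict_proba(fv.values.reshape(1, -1))[0]
    scores = {c: 0.0 for c in CLASSES}
    for c, v in zip(model.forest.classes_, pp):
        scores[c] = float(v)
    return ClassScores(scores)


def resistance_score(scores: ClassScores, prec: ClassPrecisions) -> float:
    """Precision-weighted resistance-minus-sensitivity confidence sum."""
    s, p = scores.scores, prec.precisions
    return (s["SRES"] * p.get("SRES", 0.0) + s["RES"] * p.get("RES", 0.0)
            - s["NEU"] * p.get("NEU", 0.0) - s["ISEN"] * p.get("ISEN", 0.0))


def normalize_scores(batch: list[float]) -> tuple[list[float], bool]:
    """Min-max rescale RS values within one experiment.

    Returns (NRS list, degenerate flag); an all-equal batch maps to zeros
    with the flag set.
    """
    if not batch:
        raise ValueError("empty RS batch")
    lo, hi = min(batch), max(batch)
    if hi == lo:
        return [0.0 for _ in batch], True
    return [(v - lo) / (hi - lo) for v in batch], False


def score_batch(
    model: ClassifierModel,
    fvs: list[FeatureVector],
    prec: ClassPrecisions,
) -> list[ResistanceResult]:
    """Predict, score and batch-normalise a list of feature vectors."""
    results = []
    for fv in fvs:
        sc = predict_scores(model, fv)
        results.append(ResistanceResult(
            sc, sc.predicted_class, resistance_score(sc, prec)))
    nrs, _ = normalize_scores([r.rs for r in results])
    for r, v in zip(results, nrs):
        r.nrs = v
    return results


def affinity_only_baseline(
    pairs: list[tuple[float, float, str]],
    params: dict | None = None,
    seed: int = 0,
    k: int = 10,
    fold_threshold: float = 1.2,
) -> tuple[RandomForestClassifier, CVReport, dict]:
    """Two-feature baseline using externally predicted WT/MT affinities.

    Each pair is (WT predicted affinity, MT predicted affinity, label);
    the report also counts per-instance fold changes (WT/MT ratio)
    exceeding the threshold in either direction.
    """
    clean = [(w, m, lab) for w, m, lab in pairs
             if np.isfinite(w) and np.isfinite(m)]
    skipped = len(pairs) - len(clean)
    if not clean:
        raise ValueError("no usable affinity pairs")
    X = np.array([[w, m] for w, m, _ in clean])
    y = np.array([lab for _, _, lab in clean])
    folds = [w / m if m != 0 else np.inf for w, m, _ in clean]
    p = dict(DEFAULT_RF_PARAMS)
    if params:
        p.update(params)
    proba, pred, present, k_used = _fit_predict_cv(X, y, k, seed, p)
    auc = {c: float(roc_auc_score((y == c).astype(int), proba[:, ci]))
           for ci, c in enumerate(present)}
    report = CVReport(
        auc=auc,
        precision={c: float(precision_score(y, pred, labels=[c],
                                            average="macro", zero_division=0))
                   for c in present},
        recall={c: float(recall_score(y, pred, labels=[c], average="macro",
                                      zero_division=0)) for c in present},
        mean_auc=float(np.mean(list(auc.values()))),
        kappa=float(cohen_kappa_score(y, pred)),
        confusion=confusion_matrix(y, pred, labels=list(present)),
        k=k_used, seed=seed,
    )
    p2 = dict(p)
    p2["max_features"] = min(p2["max_features"], 2)
    forest = RandomForestClassifier(random_state=seed, **p2)
    forest.fit(X, y)
    extra = {
        "fold_changes": folds,
        "n_over_threshold": sum(
            1 for f in folds
            if f >= fold_threshold or f <= 1.0 / fold_threshold
        ),
        "skipped": skipped,
    }
    return forest, report, extra
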