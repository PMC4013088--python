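"""Per-species ensemble habitat-suitability modelling.

For each species: target-group pseudo-absences (the thinned cells of all
*other* species), repeated random 20/80 test/train splits, three learners per
split (a maximum-entropy-style penalized logistic model, bagged random-forest
trees and boosted trees, each with 100 trees), held-out AUC and TSS per
replicate, a sensitivity = specificity threshold per replicate, and two
ensembles over the replicates that clear an AUC inclusion bound:

* weighted mean — member predictions weighted proportionally to AUC;
* committee average — the mean of member binary maps, which doubles as an
  agreement/uncertainty surface.

The ensemble's own presence/absence threshold is recomputed on the weighted
mean by the same sensitivity = specificity rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .covariates import CovariateStack
from .geo_core import Grid, OccurrenceTable, RasterLayer, occurrence_cells

log = logging.getLogger(__name__)

LEARNERS = ("maxent", "rf", "gbm")


@dataclass
class TrainingSet:
    """Presence and pseudo-absence cells for one species, with covariates."""

    species_code: str
    presence: np.ndarray       # (n_p, 2) row/col
    pseudo_absence: np.ndarray  # (n_a, 2) row/col
    X: np.ndarray              # covariates, presences first
    y: np.ndarray              # 1 = presence, 0 = pseudo-absence
    covariate_names: list[str]

    def __post_init__(self) -> None:
        pres = {tuple(c) for c in self.presence}
        absn = {tuple(c) for c in self.pseudo_absence}
        if pres & absn:
            raise ValueError("presence and pseudo-absence cells overlap")
        if len(self.presence) < 5:
            raise ValueError(
                f"{self.species_code}: need >= 5 presence cells, have {len(self.presence)}"
            )


@dataclass
class ModelReplicate:
    """One fitted learner on one random split, with held-out evaluation."""

    learner_id: str
    split_seed: int
    auc: float
    tss: float
    threshold: float
    prediction: RasterLayer
    model: object = field(repr=False, default=None)
    excluded: bool = False
    note: str = ""


@dataclass
class EnsembleModel:
    """Weighted-mean and committee-average ensembles for one species."""

    species_code: str
    weighted_mean: RasterLayer
    committee_avg: RasterLayer
    binary: RasterLayer
    threshold: float
    n_included: int
    replicates: list[ModelReplicate] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# training data


def select_pseudo_absences(
    all_occ: OccurrenceTable, focal: str, grid: Grid
) -> np.ndarray:
    """Target-group background: thinned cells of all non-focal species.

    Because every species was collected under the same spatially biased
    effort, using the other species' cells as pseudo-absences puts the same
    bias in both classes, so the learner sees niche signal rather than
    collection signal. Cells that also contain the focal species are
    excluded. Returns an (n, 2) array of unique row/col pairs.
    """
    if not all_occ.thinned:
        raise ValueError("occurrence table must be thinned first")
    cells = occurrence_cells(all_occ, grid)
    focal_cells = set(
        map(tuple, cells.loc[cells["species"] == focal, ["row", "col"]].to_numpy())
    )
    others = cells.loc[cells["species"] != focal, ["row", "col"]].drop_duplicates()
    pa = [c for c in map(tuple, others.to_numpy()) if c not in focal_cells]
    if not pa:
        raise ValueError(
            f"no pseudo-absence cells for {focal!r}: need occurrences of other species"
        )
    return np.array(sorted(pa), dtype=int)


def make_training_set(
    all_occ: OccurrenceTable, focal: str, stack: CovariateStack
) -> TrainingSet:
    """Assemble presences, target-group pseudo-absences and covariates."""
    grid = stack.grid
    cells = occurrence_cells(all_occ, grid)
    pres = (
        cells.loc[cells["species"] == focal, ["row", "col"]]
        .drop_duplicates()
        .to_numpy()
    )
    pa = select_pseudo_absences(all_occ, focal, grid)

    def usable(arr):
        X = stack.as_matrix(arr[:, 0], arr[:, 1])
        ok = np.isfinite(X).all(axis=1)
        return arr[ok], X[ok]

    pres, Xp = usable(pres)
    pa, Xa = usable(pa)
    return TrainingSet(
        species_code=focal,
        presence=pres,
        pseudo_absence=pa,
        X=np.vstack([Xp, Xa]),
        y=np.concatenate([np.ones(len(pres)), np.zeros(len(pa))]),
        covariate_names=stack.names,
    )


# ---------------------------------------------------------------------------
# evaluation statistics


def auc(presence_scores, absence_scores) -> float:
    """Rank-based AUC: P(presence score > absence score), ties counting 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    greater = (p[:, None] > a[None, :]).sum()
    ties = (p[:, None] == a[None, :]).sum()
    return float((greater + 0.5 * ties) / (p.size * a.size))


def tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if tp + fn <= 0 or tn + fp <= 0:
        raise ValueError("both observed classes must be non-empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens + spec - 1.0


def sens_spec_threshold(presence_scores, absence_scores) -> float:
    """Threshold (from the observed scores) where sensitivity = specificity.

    Presence is predicted at score >= t. Among candidate thresholds the one
    minimizing |Se - Sp| wins; ties go to the larger TSS, then to the lower
    threshold. Using a data-driven equal-error threshold avoids the inflated
    omission/commission of arbitrary fixed cutoffs.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    cand = np.unique(np.concatenate([p, a]))
    se = (p[None, :] >= cand[:, None]).mean(axis=1)
    sp = (a[None, :] < cand[:, None]).mean(axis=1)
    diff = np.abs(se - sp)
    tss_vals = se + sp - 1.0
    # lexicographic: min |Se-Sp|, then max TSS, then min threshold
    order = np.lexsort((cand, -tss_vals, diff))
    return float(cand[order[0]])


# ---------------------------------------------------------------------------
# learners and replicate fitting


def _make_learner(learner_id: str, seed: int):
    if learner_id == "maxent":
        # maximum-entropy-style: L2-penalized logistic regression on
        # standardized covariates, capped at 100 iterations
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=100, random_state=seed),
        )
    if learner_id == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if learner_id == "gbm":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown learner {learner_id!r}")


def _split(ts: TrainingSet, test_fraction: float, rng: np.random.Generator):
    """Stratified random split guaranteeing >= 1 test and train point per class."""
    idx_p = np.nonzero(ts.y == 1)[0]
    idx_a = np.nonzero(ts.y == 0)[0]
    out_test, out_train = [], []
    for idx in (idx_p, idx_a):
        perm = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        n_test = min(n_test, len(idx) - 1)
        out_test.append(perm[:n_test])
        out_train.append(perm[n_test:])
    return np.concatenate(out_train), np.concatenate(out_test)


def fit_replicates(
    ts: TrainingSet,
    stack: CovariateStack,
    n_reps: int = 500,
    split: float = 0.2,
    seed: int = 0,
    learners=LEARNERS,
) -> list[ModelReplicate]:
    """Fit ``n_reps`` random-split replicates of each learner.

    Each replicate draws its own stratified 20/80 test/train split, fits the
    learner on the training part, scores AUC and TSS on the held-out part
    (TSS at the replicate's own sensitivity = specificity threshold) and
    predicts suitability over the whole covariate stack. Degenerate training
    data (a single class, or constant covariates) flags the replicate as
    excluded instead of aborting the run. Deterministic given ``seed``.
    """
    if len(ts.presence) < 2:
        raise ValueError("need at least 2 presences to hold one out")
    X_all, valid = stack.full_matrix()
    rng = np.random.default_rng(seed)
    out: list[ModelReplicate] = []
    for rep in range(n_reps):
        split_seed = int(rng.integers(0, 2**31 - 1))
        srng = np.random.default_rng(split_seed)
        train, test = _split(ts, split, srng)
        Xtr, ytr = ts.X[train], ts.y[train]
        Xte, yte = ts.X[test], ts.y[test]
        degenerate = len(np.unique(ytr)) < 2 or np.all(Xtr.std(axis=0) == 0)
        for learner_id in learners:
            if degenerate:
                out.append(
                    ModelReplicate(
                        learner_id, split_seed, np.nan, np.nan, np.nan,
                        prediction=RasterLayer(stack.grid, np.full(stack.grid.shape, np.nan)),
                        excluded=True, note="degenerate training data",
                    )
                )
                continue
            model = _make_learner(learner_id, split_seed)
            model.fit(Xtr, ytr)
            score_te = model.predict_proba(Xte)[:, 1]
            p_scores = score_te[yte == 1]
            a_scores = score_te[yte == 0]
            rep_auc = auc(p_scores, a_scores)
            thr = sens_spec_threshold(p_scores, a_scores)
            rep_tss = tss(
                tp=int((p_scores >= thr).sum()),
                fn=int((p_scores < thr).sum()),
                tn=int((a_scores < thr).sum()),
                fp=int((a_scores >= thr).sum()),
            )
            pred = np.full(stack.grid.shape, np.nan)
            pred[valid] = model.predict_proba(X_all)[:, 1]
            out.append(
                ModelReplicate(
                    learner_id, split_seed, rep_auc, rep_tss, thr,
                    prediction=RasterLayer(
                        stack.grid, pred, name=f"{ts.species_code}_{learner_id}_{rep}"
                    ),
                    model=model,
                )
            )
    n_excluded = sum(r.excluded for r in out)
    if n_excluded:
        log.warning("%s: %d replicate(s) excluded as degenerate", ts.species_code, n_excluded)
    return out


def replicate_metrics(replicates: list[ModelReplicate]) -> pd.DataFrame:
    """Tidy per-replicate evaluation table (learner, AUC, TSS, threshold)."""
    return pd.DataFrame(
        {
            "learner": [r.learner_id for r in replicates],
            "auc": [r.auc for r in replicates],
            "tss": [r.tss for r in replicates],
            "threshold": [r.threshold for r in replicates],
            "excluded": [r.excluded for r in replicates],
        }
    )


# ---------------------------------------------------------------------------
# ensembling


def ensemble(
    replicates: list[ModelReplicate],
    ts: TrainingSet,
    inclusion_auc: float = 0.5,
) -> EnsembleModel:
    """Combine replicates into weighted-mean and committee-average ensembles.

    Replicates with held-out AUC strictly above ``inclusion_auc`` (0.5 = no
    better than random) are included. Weighted-mean weights are proportional
    to AUC; the committee average is the mean of member binary maps (each at
    its own threshold). The ensemble threshold is recomputed by the
    sensitivity = specificity rule on the weighted-mean scores at the
    training presences and pseudo-absences.
    """
    included = [r for r in replicates if not r.excluded and r.auc > inclusion_auc]
    if not included:
        raise ValueError(
            f"no replicate passes the AUC > {inclusion_auc} inclusion bound"
        )
    grid = included[0].prediction.grid
    weights = np.array([r.auc for r in included])
    weights = weights / weights.sum()

    wmean = np.zeros(grid.shape)
    committee = np.zeros(grid.shape)
    for w, r in zip(weights, included):
        wmean = wmean + w * r.prediction.filled(0.0)
        committee = committee + (r.prediction.filled(-np.inf) >= r.threshold)
    committee = committee / len(included)
    valid = np.ones(grid.shape, dtype=bool)
    for r in included:
        valid &= r.prediction.valid
    wmean[~valid] = np.nan
    committee = np.where(valid, committee, np.nan)

    p_scores = wmean[ts.presence[:, 0], ts.presence[:, 1]]
    a_scores = wmean[ts.pseudo_absence[:, 0], ts.pseudo_absence[:, 1]]
    p_scores = p_scores[np.isfinite(p_scores)]
    a_scores = a_scores[np.isfinite(a_scores)]
    thr = sens_spec_threshold(p_scores, a_scores)
    binary = np.where(valid, (wmean >= thr).astype(float), np.nan)

    code = ts.species_code
    return EnsembleModel(
        species_code=code,
        weighted_mean=RasterLayer(grid, wmean, f"{code}_weighted_mean"),
        committee_avg=RasterLayer(grid, committee, f"{code}_committee_avg"),
        binary=RasterLayer(grid, binary, f"{code}_binary"),
        threshold=thr,
        n_included=len(included),
        replicates=replicates,
    )


def fit_species_ensemble(
    all_occ: OccurrenceTable,
    focal: str,
    stack: CovariateStack,
    n_reps: int = 500,
    split: float = 0.2,
    seed: int = 0,
    learners=LEARNERS,
    inclusion_auc: float = 0.5,
) -> EnsembleModel:
    """Convenience: training set -> replicates -> ensemble for one species."""
    ts = make_training_set(all_occ, focal, stack)
    reps = fit_replicates(ts, stack, n_reps=n_reps, split=split, seed=seed, learners=learners)
    return ensemble(reps, ts, inclusion_auc=inclusion_auc)


# ---------------------------------------------------------------------------
# interpretation


def _predict_matrix(model_like, X: np.ndarray) -> np.ndarray:
    """Suitability scores for a replicate, an ensemble, or a bare estimator."""
    if isinstance(model_like, ModelReplicate):
        return model_like.model.predict_proba(X)[:, 1]
    if isinstance(model_like, EnsembleModel):
        included = [
            r for r in model_like.replicates if not r.excluded and r.model is not None
        ]
        w = np.array([r.auc for r in included])
        w = w / w.sum()
        return sum(
            wi * r.model.predict_proba(X)[:, 1] for wi, r in zip(w, included)
        )
    return model_like.predict_proba(X)[:, 1]


def variable_importance(
    model_like, stack: CovariateStack, n_shuffles: int = 5, seed: int = 0
) -> dict[str, float]:
    """Permutation importance: 1 - Pearson r(reference, shuffled predictions).

    Each covariate's column is permuted across cells ``n_shuffles`` times;
    the mean correlation loss is the importance, clipped at 0. A model with
    constant predictions has undefined importances (NaN everywhere).
    """
    X, _ = stack.full_matrix()
    ref = _predict_matrix(model_like, X)
    if np.std(ref) == 0:
        return {name: np.nan for name in stack.names}
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for j, name in enumerate(stack.names):
        losses = []
        for _ in range(n_shuffles):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = _predict_matrix(model_like, Xp)
            r = np.corrcoef(ref, pred)[0, 1] if np.std(pred) > 0 else 0.0
            losses.append(1.0 - r)
        out[name] = float(max(0.0, np.mean(losses)))
    return out


def response_curve(
    model_like, stack: CovariateStack, covariate: str, n_points: int = 50
) -> pd.DataFrame:
    """Evaluation-strip response: sweep one covariate, hold the rest at median.

    Returns a DataFrame with columns ``value`` (the swept covariate, over its
    observed range) and ``prediction``.
    """
    if covariate not in stack:
        raise KeyError(f"unknown covariate {covariate!r}")
    X, _ = stack.full_matrix()
    med = np.median(X, axis=0)
    j = stack.names.index(covariate)
    values = np.linspace(X[:, j].min(), X[:, j].max(), n_points)
    strip = np.tile(med, (n_points, 1))
    strip[:, j] = values
    preds = _predict_matrix(model_like, strip)
    return pd.DataFrame({"value": values, "prediction": preds})
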