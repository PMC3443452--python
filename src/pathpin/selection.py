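"""Network-constrained greedy selection of pathway markers.

The search treats dysregulated-pathway identification as forward feature
selection over pathway activities: the first marker is the single pathway
whose activity best separates disease from control under repeated stratified
five-fold cross-validation of an RBF-kernel SVM (scored by AUC); every later
candidate must be a PIN neighbor of the already-selected set and is accepted
only if it improves the mean cross-validated AUC beyond a small tolerance.
The result is a minimal connected set of pathways that best discriminates the
two classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .activity import ActivityMatrix
from .io import InputError, SampleLabels
from .pin import PathwayNetwork

logger = logging.getLogger(__name__)


@dataclass
class EvaluationConfig:
    """Cross-validation and SVM settings for marker evaluation.

    ``n_repeats`` is used for the definitive evaluation of a feature set;
    ``search_repeats`` (fewer) scores candidates inside the greedy loop, with
    the accepted final set re-scored at ``n_repeats``. Set ``search_repeats``
    equal to ``n_repeats`` to keep the full repeat count throughout.
    """

    n_folds: int = 5
    n_repeats: int = 100
    search_repeats: int = 10
    kernel: str = "rbf"
    svm_cost: float = 1.0
    rbf_gamma: float | str = "auto"  # "auto" = 1 / n_features
    seed: int = 0
    improvement_tol: float = 1e-3
    stratified: bool = True
    frontier: str = "all-selected"  # or "first-only"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise InputError("n_folds must be >= 2")
        if self.n_repeats < 1 or self.search_repeats < 1:
            raise InputError("repeat counts must be >= 1")
        if self.kernel != "rbf":
            raise InputError("only the RBF kernel is supported")
        if self.frontier not in ("all-selected", "first-only"):
            raise InputError("frontier must be 'all-selected' or 'first-only'")


@dataclass
class SelectionStep:
    pathway: str
    pool_size: int
    mean_auc: float
    auc_std: float


@dataclass
class SelectionTrace:
    """Ordered record of the greedy search."""

    steps: list[SelectionStep] = field(default_factory=list)
    final_set: list[str] = field(default_factory=list)
    final_auc: float = float("nan")
    final_auc_std: float = float("nan")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tpathway\tmean_auc\tauc_std\tpool_size\n")
            for i, s in enumerate(self.steps, start=1):
                fh.write(f"{i}\t{s.pathway}\t{s.mean_auc:.6f}\t{s.auc_std:.6f}\t{s.pool_size}\n")

    def write_markers(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pathway\n")
            for p in self.final_set:
                fh.write(p + "\n")

    def to_dict(self) -> dict:
        return {
            "steps": [vars(s) for s in self.steps],
            "final_set": self.final_set,
            "final_auc": self.final_auc,
            "final_auc_std": self.final_auc_std,
        }


def auc_score(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula.

    Equals the probability that a random positive's score exceeds a random
    negative's, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _feature_rows(activity: ActivityMatrix, features: list[str]) -> np.ndarray:
    missing = [f for f in features if f not in set(activity.pathway_ids)]
    if missing:
        raise InputError(f"features not in activity matrix: {missing[:5]}")
    return activity.scores.loc[list(features)].to_numpy().T  # samples x features


def evaluate_feature_set(
    activity: ActivityMatrix,
    features: list[str],
    labels: SampleLabels,
    cfg: EvaluationConfig,
    n_repeats: int | None = None,
) -> dict[str, float]:
    """Repeated k-fold CV of an RBF SVM on the given activity rows.

    Per repeat, samples are split into stratified folds seeded by
    ``cfg.seed + repeat``; out-of-fold decision values are pooled into one
    ROC per repeat. Returns the mean and standard deviation of the per-repeat
    AUCs.
    """
    if not features:
        raise InputError("feature set is empty")
    reps = cfg.n_repeats if n_repeats is None else n_repeats
    X = _feature_rows(activity, list(features))
    y = labels.binary(activity.sample_ids)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < cfg.n_folds:
        raise InputError(
            f"each class needs >= n_folds={cfg.n_folds} samples (got {n_pos}/{n_neg})"
        )
    gamma = cfg.rbf_gamma if cfg.rbf_gamma != "auto" else 1.0 / X.shape[1]
    aucs = np.empty(reps)
    for r in range(reps):
        splitter_cls = StratifiedKFold if cfg.stratified else KFold
        splitter = splitter_cls(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed + r)
        decision = np.empty(len(y))
        for train, test in splitter.split(X, y):
            clf = SVC(C=cfg.svm_cost, kernel="rbf", gamma=gamma)
            clf.fit(X[train], y[train])
            decision[test] = clf.decision_function(X[test])
        aucs[r] = auc_score(decision, y)
    return {"mean_auc": float(aucs.mean()), "auc_std": float(aucs.std(ddof=0))}


def _best_candidate(
    activity: ActivityMatrix,
    base: list[str],
    candidates: list[str],
    labels: SampleLabels,
    cfg: EvaluationConfig,
) -> tuple[str | None, dict[str, float] | None]:
    """Highest-scoring candidate appended to ``base``; lexicographic tie-break.

    Candidates are scanned in sorted order and must strictly beat the incumbent
    best, so the smallest identifier wins exact ties. All candidates are scored
    on identical fold partitions (same seeds).
    """
    best_name: str | None = None
    best: dict[str, float] | None = None
    for cand in sorted(candidates):
        res = evaluate_feature_set(activity, base + [cand], labels, cfg, cfg.search_repeats)
        if best is None or res["mean_auc"] > best["mean_auc"]:
            best_name, best = cand, res
    return best_name, best


def greedy_select(
    activity: ActivityMatrix,
    pin: PathwayNetwork,
    labels: SampleLabels,
    cfg: EvaluationConfig,
) -> SelectionTrace:
    """Greedy forward selection of pathway markers constrained to the PIN.

    Step 1 picks the single pathway (over all PIN nodes) with the highest mean
    CV AUC. Each later step scores every unselected PIN neighbor of the
    selected set appended to it and accepts the best one iff it improves the
    incumbent mean AUC by more than ``cfg.improvement_tol``; the search stops
    when no candidate improves or the frontier is empty. The final set is then
    re-scored at the full ``cfg.n_repeats``.
    """
    nodes = sorted(pin.nodes)
    if not nodes:
        raise InputError("pathway network has no nodes")
    available = set(activity.pathway_ids)
    missing = [n for n in nodes if n not in available]
    if missing:
        raise InputError(f"PIN nodes without activity rows: {missing[:5]}")

    trace = SelectionTrace()
    first, res = _best_candidate(activity, [], nodes, labels, cfg)
    assert first is not None and res is not None
    selected = [first]
    incumbent = res["mean_auc"]
    trace.steps.append(SelectionStep(first, len(nodes), res["mean_auc"], res["auc_std"]))
    logger.info("step 1: %s (mean AUC %.4f over %d candidates)", first, incumbent, len(nodes))

    while True:
        if cfg.frontier == "first-only":
            frontier = pin.neighbors(selected[0]) - set(selected)
        else:
            frontier = set().union(*(pin.neighbors(p) for p in selected)) - set(selected)
        frontier &= set(nodes)
        if not frontier:
            break
        cand, res = _best_candidate(activity, selected, sorted(frontier), labels, cfg)
        assert cand is not None and res is not None
        if res["mean_auc"] <= incumbent + cfg.improvement_tol:
            break
        selected.append(cand)
        incumbent = res["mean_auc"]
        trace.steps.append(SelectionStep(cand, len(frontier), res["mean_auc"], res["auc_std"]))
        logger.info(
            "step %d: + %s (mean AUC %.4f over %d candidates)",
            len(selected),
            cand,
            incumbent,
            len(frontier),
        )

    trace.final_set = list(selected)
    final = evaluate_feature_set(activity, selected, labels, cfg, cfg.n_repeats)
    trace.final_auc = final["mean_auc"]
    trace.final_auc_std = final["auc_std"]
    return trace


def write_manifest(path: str | Path, cfg: EvaluationConfig, extra: dict | None = None) -> None:
    """JSON run manifest: all parameters plus key software versions."""
    import sklearn

    import pathpin

    payload = {
        "config": {k: v for k, v in vars(cfg).items()},
        "versions": {
            "pathpin": pathpin.__version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
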