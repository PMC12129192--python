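"""Machine-learning multi-omics integration baselines.

Three strategies over the ordered feature blocks (BDI clinical, PRS,
top methylation markers), each evaluated by seeded stratified CV with
all preprocessing fit on training folds only:

* **concatenation** — z-score and column-concatenate the blocks, run each
  classifier of a configurable set (defaults: the five core learners plus
  decision tree, gradient boosting and MLP — eight in total);
* **transformation** — per block, fit a PCA on the training fold and
  project both splits to the block's target dimension (defaults 3/4/5 for
  the C / C+P / C+P+M ladder, clamped to the block width), concatenate,
  then classify;
* **model-based** — per block, pick the base learner (KNN, LR, NB, SVM,
  RF) minimizing inner-CV log-loss on the training fold, then soft-vote
  (unweighted mean of per-block class probabilities; argmax ties resolve
  to class 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .metrics import MetricsReport, fold_metrics, stratified_folds

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "OmicsBlocks",
    "default_classifier_set",
    "base_learner_set",
    "concat_integrate",
    "transform_integrate",
    "model_based_integrate",
    "strategy_ladder",
    "LADDERS",
]

LADDERS = {"C": ["clinical_bdi"], "CP": ["clinical_bdi", "prs"],
           "CPM": ["clinical_bdi", "prs", "methylation_top"]}


@dataclass
class OmicsBlocks:
    """Row-aligned named feature blocks in fixed order."""

    clinical_bdi: np.ndarray           # n x 4
    prs: np.ndarray                    # n x 1
    methylation_top: np.ndarray        # n x 10

    def __post_init__(self):
        self.clinical_bdi = np.atleast_2d(np.asarray(self.clinical_bdi, float))
        self.prs = np.asarray(self.prs, float)
        if self.prs.ndim == 1:
            self.prs = self.prs[:, None]
        self.methylation_top = np.atleast_2d(
            np.asarray(self.methylation_top, float))
        ns = {a.shape[0] for a in (self.clinical_bdi, self.prs,
                                   self.methylation_top)}
        if len(ns) != 1:
            raise ValueError("blocks must share the row count")
        for name in ("clinical_bdi", "prs", "methylation_top"):
            if np.isnan(getattr(self, name)).any():
                raise ValueError(f"block {name} contains missing values")

    def get(self, names) -> list[np.ndarray]:
        return [getattr(self, n) for n in names]

    @property
    def n_samples(self) -> int:
        return self.clinical_bdi.shape[0]


def _scaled(clf):
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    return make_pipeline(StandardScaler(), clf)


def base_learner_set(seed: int = 0) -> dict:
    """The five core probabilistic learners: KNN, LR, NB, SVM, RF."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    return {
        "KNN": _scaled(KNeighborsClassifier()),
        "LR": _scaled(LogisticRegression(max_iter=2000)),
        "NB": _scaled(GaussianNB()),
        "SVM": _scaled(SVC(probability=True, random_state=seed)),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed,
                                     n_jobs=1),
    }


def default_classifier_set(seed: int = 0) -> dict:
    """Eight classifiers for concatenation-based integration."""
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    clfs = base_learner_set(seed)
    clfs.update({
        "DT": DecisionTreeClassifier(random_state=seed),
        "GB": GradientBoostingClassifier(random_state=seed),
        "MLP": _scaled(MLPClassifier(hidden_layer_sizes=(16,), max_iter=800,
                                     random_state=seed)),
    })
    return clfs


def _clone(clf):
    from sklearn.base import clone
    return clone(clf)


def concat_integrate(blocks, y, block_names=None, classifier_set=None,
                     n_folds: int = 5, seed: int = 0, fold_plan=None
                     ) -> dict[str, MetricsReport]:
    """Column-concatenate the selected blocks and CV each classifier.

    Scaling lives inside each classifier pipeline, so it is fit on the
    training folds only. A classifier failing on a fold is logged and its
    aggregate covers the completed folds.
    """
    if isinstance(blocks, OmicsBlocks):
        names = block_names or list(LADDERS["CPM"])
        X = np.hstack(blocks.get(names))
    else:
        X = np.asarray(blocks, dtype=float)
    y = np.asarray(y).astype(int)
    classifier_set = classifier_set or default_classifier_set(seed)
    plan = fold_plan or stratified_folds(y, n_folds=n_folds, seed=seed)
    out = {}
    for name, proto in classifier_set.items():
        rows = []
        for tr, te in plan:
            clf = _clone(proto)
            try:
                clf.fit(X[tr], y[tr])
                rows.append(fold_metrics(y[te], clf.predict(X[te])))
            except Exception as e:          # noqa: BLE001 - fold failure path
                logger.warning("concat_integrate: %s failed on a fold: %s",
                               name, e)
        if rows:
            out[name] = MetricsReport.from_folds(
                rows, seed=seed, config_snapshot={"classifier": name,
                                                  "strategy": "concat"})
    return out


def transform_integrate(blocks: OmicsBlocks, y, block_names=None,
                        reduced_dims=(3, 4, 5), classifier_set=None,
                        n_folds: int = 5, seed: int = 0, fold_plan=None
                        ) -> dict[str, MetricsReport]:
    """Per-block train-fold PCA projection, then concatenated CV
    classification. Target dims beyond a block's width are clamped."""
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    names = block_names or list(LADDERS["CPM"])
    mats = blocks.get(names)
    y = np.asarray(y).astype(int)
    dims = list(reduced_dims)[:len(mats)]
    while len(dims) < len(mats):
        dims.append(mats[len(dims)].shape[1])
    classifier_set = classifier_set or default_classifier_set(seed)
    plan = fold_plan or stratified_folds(y, n_folds=n_folds, seed=seed)
    out = {}
    for name, proto in classifier_set.items():
        rows = []
        for tr, te in plan:
            parts_tr, parts_te = [], []
            for M, dim in zip(mats, dims):
                d = min(dim, M.shape[1], len(tr))
                if d < dim:
                    logger.warning("transform_integrate: dim clamped to %d "
                                   "for a width-%d block", d, M.shape[1])
                sc = StandardScaler().fit(M[tr])
                Ztr, Zte = sc.transform(M[tr]), sc.transform(M[te])
                if d == M.shape[1]:
                    parts_tr.append(Ztr)
                    parts_te.append(Zte)
                else:
                    pca = PCA(n_components=d, random_state=seed).fit(Ztr)
                    parts_tr.append(pca.transform(Ztr))
                    parts_te.append(pca.transform(Zte))
            clf = _clone(proto)
            try:
                clf.fit(np.hstack(parts_tr), y[tr])
                rows.append(fold_metrics(y[te], clf.predict(np.hstack(parts_te))))
            except Exception as e:          # noqa: BLE001
                logger.warning("transform_integrate: %s failed on a fold: %s",
                               name, e)
        if rows:
            out[name] = MetricsReport.from_folds(
                rows, seed=seed, config_snapshot={"classifier": name,
                                                  "strategy": "transform",
                                                  "reduced_dims": dims})
    return out


def _inner_log_loss(proto, X, y, seed: int, n_inner: int = 3) -> float:
    """Mean inner-CV log-loss of a learner on the training fold."""
    from sklearn.metrics import log_loss
    counts = np.bincount(y, minlength=2)
    n_inner = min(n_inner, counts[counts > 0].min())
    if n_inner < 2:
        return np.inf
    plan = stratified_folds(y, n_folds=n_inner, seed=seed)
    losses = []
    for tr, te in plan:
        clf = _clone(proto)
        clf.fit(X[tr], y[tr])
        losses.append(log_loss(y[te], clf.predict_proba(X[te]),
                               labels=[0, 1]))
    return float(np.mean(losses))


def model_based_integrate(blocks: OmicsBlocks, y, block_names=None,
                          base_learners=None, n_folds: int = 5,
                          seed: int = 0, fold_plan=None
                          ) -> tuple[MetricsReport, dict[str, list[str]]]:
    """Per-block learner selection by inner-CV log-loss, soft-vote fusion.

    Returns (MetricsReport, per-block chosen learner names per fold).
    Learners without a predict_proba are excluded from the candidate set
    with a warning. Soft-vote ties resolve to class 0 (argmax convention).
    """
    names = block_names or list(LADDERS["CPM"])
    mats = blocks.get(names)
    y = np.asarray(y).astype(int)
    base_learners = base_learners or base_learner_set(seed)
    usable = {}
    for lname, proto in base_learners.items():
        est = proto.steps[-1][1] if hasattr(proto, "steps") else proto
        if not (hasattr(est, "predict_proba") or
                getattr(est, "probability", True)):
            logger.warning("model_based_integrate: %s lacks probability "
                           "output; excluded", lname)
            continue
        usable[lname] = proto
    plan = fold_plan or stratified_folds(y, n_folds=n_folds, seed=seed)
    rows, chosen = [], {n: [] for n in names}
    for tr, te in plan:
        probs = []
        for bname, M in zip(names, mats):
            losses = {ln: _inner_log_loss(proto, M[tr], y[tr], seed)
                      for ln, proto in usable.items()}
            best = min(sorted(losses), key=lambda ln: losses[ln])
            chosen[bname].append(best)
            clf = _clone(usable[best])
            clf.fit(M[tr], y[tr])
            probs.append(clf.predict_proba(M[te]))
        vote = np.mean(probs, axis=0)
        yhat = vote.argmax(axis=1)          # ties -> class 0
        rows.append(fold_metrics(y[te], yhat, scores=vote[:, 1]))
    report = MetricsReport.from_folds(
        rows, seed=seed,
        config_snapshot={"strategy": "model", "blocks": names})
    return report, chosen


def strategy_ladder(blocks: OmicsBlocks, y, n_folds: int = 5, seed: int = 0
                    ) -> dict[str, dict[str, MetricsReport]]:
    """The 3x3 grid: integration strategy x block ladder (C, C+P, C+P+M).

    For concatenation and transformation the reported entry is the
    best-MCC classifier of the set (its name is recorded in the snapshot);
    model-based reports the soft vote. All cells share one fold plan.
    """
    y = np.asarray(y).astype(int)
    plan = stratified_folds(y, n_folds=n_folds, seed=seed)
    out: dict[str, dict[str, MetricsReport]] = {
        "concat": {}, "transform": {}, "model": {}}
    for ladder, names in LADDERS.items():
        cres = concat_integrate(blocks, y, block_names=names, seed=seed,
                                fold_plan=plan)
        best = max(sorted(cres), key=lambda k: cres[k].aggregate["mcc"])
        out["concat"][ladder] = cres[best]
        tres = transform_integrate(blocks, y, block_names=names, seed=seed,
                                   fold_plan=plan)
        best = max(sorted(tres), key=lambda k: tres[k].aggregate["mcc"])
        out["transform"][ladder] = tres[best]
        out["model"][ladder], _ = model_based_integrate(
            blocks, y, block_names=names, seed=seed, fold_plan=plan)
    return out
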