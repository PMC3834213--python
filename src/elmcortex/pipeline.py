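"""End-to-end orchestration of the classification workflow.

Stage order is fixed: min-max normalization -> Fisher-score ranking ->
nested experimental datasets (accuracy curve) -> sequential forward
selection over the top-ranked pool -> final validation (ROC/AUC and
permutation test).  Each stage is individually invokable; reports are
plain-text tables in the layout standard for such analyses plus tidy CSV
files, and every run can emit a machine-readable provenance record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifiers import ELMClassifier, SVMClassifier
from .elm import ELMConfig
from .errors import ValidationError
from .evaluation import (
    EvaluationResult,
    PermutationResult,
    ROCCurve,
    loocv,
    permutation_test,
    roc_curve,
    sample_size_sweep,
)
from .schema import FeatureTable, descriptor_for_index, normalize_minmax
from .selection import FScoreRanking, SFSTrace, cumulative_datasets, fscore, sfs
from .svm import SVMConfig

logger = logging.getLogger("elmcortex")

CLASSIFIER_NAMES = ("elm", "svm_linear", "svm_rbf")


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline; the seed is mandatory."""

    seed: int
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    normalize: bool = True
    per_fold_normalization: bool = False
    elm: ELMConfig = field(default_factory=ELMConfig)
    svm_linear: SVMConfig = field(default_factory=lambda: SVMConfig(kernel="linear"))
    svm_rbf: SVMConfig = field(default_factory=lambda: SVMConfig(kernel="rbf"))
    nested_grid_search: bool = False
    k_max: int = 340
    sfs_pool_size: int = 46
    sfs_max_steps: int = 19
    sfs_criterion_classifier: str = "elm"
    n_perm: int = 1000
    n_init_repeats: int = 20
    output_dir: Optional[Path] = None

    def __post_init__(self):
        if not self.classifiers:
            raise ValidationError("configure at least one classifier")
        for name in self.classifiers:
            if name not in CLASSIFIER_NAMES:
                raise ValidationError(f"unknown classifier {name!r}")
        if self.sfs_criterion_classifier not in self.classifiers:
            raise ValidationError("SFS criterion classifier must be configured")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "elm" in raw:
            raw["elm"] = ELMConfig(**raw["elm"])
        for key in ("svm_linear", "svm_rbf"):
            if key in raw:
                raw[key] = SVMConfig(kernel=key.split("_")[1], **raw[key])
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        return cls(**raw)

    def provenance(self) -> dict:
        import sklearn

        import elmcortex

        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        return {
            "config": plain(self),
            "versions": {
                "python": sys.version.split()[0],
                "elmcortex": elmcortex.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }


class _PerFoldNormalizer:
    """Wrap a classifier so min-max scaling is fit on training rows only."""

    def __init__(self, inner):
        self.inner = inner
        self.name = inner.name
        self.stochastic = inner.stochastic

    def fit(self, X, y, seed):
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span = np.where(span == 0, 1.0, span)
        fitted = self.inner.fit((X - lo) / span, y, seed)
        outer = self

        class _Fitted:
            def scores(self, Xt):
                Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
                return fitted.scores((Xt - lo) / span)

            def predict(self, Xt):
                Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
                return fitted.predict((Xt - lo) / span)

        return _Fitted()


def build_classifiers(config: PipelineConfig) -> dict:
    """Fresh classifier objects for one experimental dataset."""
    out = {}
    for name in config.classifiers:
        if name == "elm":
            clf = ELMClassifier(config.elm)
        elif name == "svm_linear":
            clf = SVMClassifier(config.svm_linear, nested=config.nested_grid_search,
                                name="svm_linear")
        else:
            clf = SVMClassifier(config.svm_rbf, nested=config.nested_grid_search,
                                name="svm_rbf")
        if config.per_fold_normalization:
            clf = _PerFoldNormalizer(clf)
        out[name] = clf
    return out


def prepare_table(table: FeatureTable, config: PipelineConfig) -> FeatureTable:
    if config.normalize and not config.per_fold_normalization \
            and not table.normalized:
        return normalize_minmax(table)
    return table


def _feature_label(table: FeatureTable, index: int) -> str:
    for d in table.descriptors:
        if d.index == index:
            return d.label()
    return f"[{index}]"


_DISPLAY = {"elm": "ELM", "svm_linear": "SVM Linear", "svm_rbf": "SVM RBF"}


def format_ed_report(results: list[EvaluationResult], table: FeatureTable,
                     classifier_names: Sequence[str], title: str) -> str:
    """Per-experimental-dataset text table:
    ED number, added feature [index, measure, region], training accuracy
    mean +/- SD and testing accuracy per classifier; the best testing
    accuracy per classifier is starred."""
    names = list(classifier_names)
    best = {n: max(r.results[n].test_acc for r in results) for n in names}
    header1 = (f"{'ED':>3}  {'Added feature':<38}"
               + "".join(f"{_DISPLAY[n] + ' train':>22}" for n in names)
               + "".join(f"{_DISPLAY[n] + ' test':>16}" for n in names))
    lines = [title, "=" * len(header1), header1, "-" * len(header1)]
    prev: set[int] = set()
    for r in results:
        added = [i for i in r.feature_subset if i not in prev]
        label = _feature_label(table, added[0]) if len(added) == 1 else \
            "+".join(str(i) for i in added)
        prev = set(r.feature_subset)
        row = f"{r.ed_id:>3}  {label:<38}"
        for n in names:
            ev = r.results[n]
            row += f"{ev.train_acc_mean:>14.2f}±{ev.train_acc_sd:<7.2f}"
        for n in names:
            ev = r.results[n]
            star = "*" if ev.test_acc == best[n] else " "
            row += f"{ev.test_acc:>15.2f}{star}"
        lines.append(row)
    lines.append("-" * len(header1))
    lines.append("* best testing accuracy for that classifier")
    return "\n".join(lines) + "\n"


def results_dataframe(results: list[EvaluationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for name, ev in r.results.items():
            rows.append({"ed": r.ed_id,
                         "features": " ".join(map(str, r.feature_subset)),
                         "classifier": name,
                         "train_acc_mean": ev.train_acc_mean,
                         "train_acc_sd": ev.train_acc_sd,
                         "test_acc": ev.test_acc})
    return pd.DataFrame(rows)


def _ed_seed(config: PipelineConfig, ed_id: int) -> int:
    return (config.seed * 100003 + ed_id) % (2 ** 31)


def _evaluate_subset(table: FeatureTable, subset: Sequence[int],
                     config: PipelineConfig, ed_id: int) -> EvaluationResult:
    clfs = build_classifiers(config)
    sub = table.select_features(subset)
    for clf in clfs.values():
        inner = getattr(clf, "inner", clf)
        if isinstance(inner, SVMClassifier) and not inner.nested:
            inner.tune(sub.values, sub.labels)
    return loocv(table, subset, list(clfs.values()), seed=_ed_seed(config, ed_id),
                 n_init_repeats=config.n_init_repeats, ed_id=ed_id)


def run_fscore_curve(table: FeatureTable, config: PipelineConfig):
    """Accuracy curve over nested top-k experimental datasets.

    Returns (ranking, results, report).  For each ED the SVM baselines
    are re-tuned by grid search on that ED (once, not per fold, unless
    nested_grid_search is set), the default protocol.
    """
    t0 = time.perf_counter()
    table = prepare_table(table, config)
    ranking = fscore(table)
    prefixes = cumulative_datasets(ranking, config.k_max)
    results = []
    for ed_id, subset in enumerate(prefixes, start=1):
        res = _evaluate_subset(table, subset, config, ed_id)
        results.append(res)
        logger.info("ED %d/%d: %s", ed_id, len(prefixes),
                    ", ".join(f"{n}={e.test_acc:.2f}%"
                              for n, e in res.results.items()))
    report = format_ed_report(
        results, table, config.classifiers,
        "Training and testing accuracy over nested F-score experimental datasets")
    logger.info("curve stage: %.1f s", time.perf_counter() - t0)
    return ranking, results, report


def run_sfs_stage(table: FeatureTable, config: PipelineConfig,
                  ranking: Optional[FScoreRanking] = None):
    """Sequential forward selection over the top-ranked feature pool.

    The SFS criterion is the LOOCV testing accuracy of the configured
    criterion classifier (default ELM); every prefix of the resulting
    path is then evaluated with all configured classifiers for the
    report.  Returns (trace, results, report).
    """
    t0 = time.perf_counter()
    table = prepare_table(table, config)
    if ranking is None:
        ranking = fscore(table)
    pool = ranking.top(min(config.sfs_pool_size, len(ranking.order)))

    crit_name = config.sfs_criterion_classifier
    cache: dict[tuple[int, ...], float] = {}

    def criterion(subset: tuple[int, ...]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            clfs = build_classifiers(config)
            clf = clfs[crit_name]
            inner = getattr(clf, "inner", clf)
            if isinstance(inner, SVMClassifier) and not inner.nested:
                sub = table.select_features(key)
                inner.tune(sub.values, sub.labels)
            cache[key] = loocv(table, key, clf,
                               seed=_ed_seed(config, 0),
                               n_init_repeats=2)[crit_name].test_acc
        return cache[key]

    trace = sfs(pool, criterion, max_steps=config.sfs_max_steps)
    results = []
    path = [f for f, _ in trace.steps]
    for ed_id in range(1, len(path) + 1):
        res = _evaluate_subset(table, path[:ed_id], config, ed_id)
        results.append(res)
        logger.info("SFS step %d: feature %d, %s", ed_id, path[ed_id - 1],
                    ", ".join(f"{n}={e.test_acc:.2f}%"
                              for n, e in res.results.items()))
    report = format_ed_report(
        results, table, config.classifiers,
        "Training and testing accuracy along the SFS path")
    if len(results) >= 2 and len(config.classifiers) >= 2:
        from .evaluation import paired_comparison

        primary = config.classifiers[0]
        lines = []
        for other in config.classifiers[1:]:
            t_stat, p = paired_comparison(
                [r[primary].test_acc for r in results],
                [r[other].test_acc for r in results])
            lines.append(f"paired t-test {_DISPLAY[primary]} vs "
                         f"{_DISPLAY[other]} over {len(results)} EDs: "
                         f"t = {t_stat:.3f}, p = {p:.4g}")
        report += "\n".join(lines) + "\n"
    logger.info("sfs stage: %.1f s", time.perf_counter() - t0)
    return trace, results, report


def format_feature_report(table: FeatureTable, subset: Sequence[int]) -> str:
    """Selected-feature listing grouped by lobe (index, measure, region)."""
    rows = []
    for idx in subset:
        d = next((dd for dd in table.descriptors if dd.index == idx), None)
        if d is None or not d.is_standard:
            rows.append(("?", f"[{idx}]"))
        else:
            rows.append((d.lobe or "?", d.label()))
    lines = ["Selected features by lobe", "-" * 40]
    for lobe in sorted({lobe for lobe, _ in rows}):
        lines.append(f"{lobe.capitalize()}:")
        for l, label in rows:
            if l == lobe:
                lines.append(f"    {label}")
    return "\n".join(lines) + "\n"


def run_final_validation(table: FeatureTable, config: PipelineConfig,
                         subset: Sequence[int]):
    """ROC/AUC for every classifier on LOOCV scores of the chosen subset
    plus a permutation test for the primary (first configured)
    classifier.  Returns (result, rocs, perm, report)."""
    subset = tuple(int(i) for i in subset)
    if not subset:
        raise ValidationError("feature subset is empty")
    t0 = time.perf_counter()
    table = prepare_table(table, config)
    result = _evaluate_subset(table, subset, config, ed_id=len(subset))
    rocs = {name: roc_curve(ev.fold_scores, result.true_labels)
            for name, ev in result.results.items()}
    primary = config.classifiers[0]
    clfs = build_classifiers(config)
    clf = clfs[primary]
    inner = getattr(clf, "inner", clf)
    if isinstance(inner, SVMClassifier) and not inner.nested:
        sub = prepare_table(table, config).select_features(subset)
        inner.tune(sub.values, sub.labels)
    perm = permutation_test(table, subset, clf, n_perm=config.n_perm,
                            seed=config.seed)
    lines = ["Final validation", "=" * 40,
             f"Feature subset ({len(subset)}): "
             + " ".join(map(str, subset)), ""]
    for name in config.classifiers:
        ev = result.results[name]
        lines.append(f"{_DISPLAY[name]:<12} LOOCV test acc {ev.test_acc:6.2f}%   "
                     f"AUC {rocs[name].auc:.4f}")
    lines += ["",
              f"Permutation test ({primary}, {config.n_perm} permutations): "
              f"observed {perm.observed_rate:.2f}%, p = {perm.p_value:.4g}",
              "",
              format_feature_report(table, subset)]
    logger.info("validation stage: %.1f s", time.perf_counter() - t0)
    return result, rocs, perm, "\n".join(lines)


def run_sample_size_sweep(table: FeatureTable, config: PipelineConfig,
                          subset: Sequence[int],
                          sizes: Sequence[int] = tuple(range(10, 111, 10)),
                          n_repeats: int = 1):
    """Balanced sub-cohort accuracy sweep; returns (DataFrame, report)."""
    table = prepare_table(table, config)
    clfs = build_classifiers(config)
    for clf in clfs.values():
        inner = getattr(clf, "inner", clf)
        if isinstance(inner, SVMClassifier) and not inner.nested:
            sub = table.select_features(subset)
            inner.tune(sub.values, sub.labels)
    df = sample_size_sweep(table, subset, list(clfs.values()), sizes,
                           seed=config.seed, n_repeats=n_repeats)
    agg = (df.groupby(["size", "classifier"], sort=True)
             [["train_acc_mean", "test_acc"]].mean().reset_index())
    header = (f"{'Size':>5}" + "".join(f"{_DISPLAY[n] + ' train':>18}"
                                       for n in config.classifiers)
              + "".join(f"{_DISPLAY[n] + ' test':>18}" for n in config.classifiers))
    lines = ["Accuracy vs experimental dataset size", "=" * len(header), header,
             "-" * len(header)]
    for size in sorted(set(agg["size"])):
        row = f"{size:>5}"
        for col in ("train_acc_mean", "test_acc"):
            for n in config.classifiers:
                v = agg[(agg["size"] == size)
                        & (agg["classifier"] == n)][col].iloc[0]
                row += f"{v:>18.2f}"
        lines.append(row)
    return df, "\n".join(lines) + "\n"


def write_outputs(output_dir, report: str, name: str,
                  df: Optional[pd.DataFrame] = None,
                  provenance: Optional[dict] = None) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}.txt").write_text(report)
    if df is not None:
        df.to_csv(out / f"{name}.csv", index=False)
    if provenance is not None:
        (out / f"{name}_provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True))
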