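"""Quality gating, feature ranking and LDA classification.

The modelling chain mirrors standard e-nose chemometrics practice:

1. replicate-uncertainty gate — a sample whose replicate cycles disagree by
   more than 10% relative spread in their R/R0 minima is excluded;
2. 3-sigma within-class outlier screen on the feature matrix;
3. random-forest impurity ranking to select the most informative features;
4. linear discriminant analysis evaluated by leave-one-out
   cross-validation, with ranking and scaling re-fit inside every fold so
   the held-out observation never leaks into selection.

When replicate cycles of one physical sample are separate observations,
cross-validation leaves the whole sample out (grouped folds), preventing
replicate leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.preprocessing import StandardScaler

from . import voc as voc_inventory
from .features import FEATURE_NAMES, featurize_dataset, impute_median
from .synthetic import (
    CycleSpec,
    default_sensor_models,
    simulate_dataset,
    simulate_voc_table,
)

logger = logging.getLogger(__name__)

DEFAULT_K_FEATURES = 7  # size of the selected-feature panel
DEFAULT_N_TREES = 300


@dataclass
class QcReport:
    """Replicate-uncertainty audit of a feature table."""

    table: pd.DataFrame  # one row per (sample, sensor): rsd + pass flag
    threshold: float
    passed_samples: list[str]
    failed_samples: list[str]

    @property
    def n_excluded(self) -> int:
        return len(self.failed_samples)


@dataclass
class LdaResult:
    """LOOCV-evaluated discriminant model of one classification task."""

    projections: pd.DataFrame  # observations x axes, with labels
    loocv_predictions: pd.Series
    confusion: pd.DataFrame
    accuracy: float
    selected_features: list[str]
    axis_names: list[str] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)


def _feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in df.columns if "__" in c]
    return df[cols].to_numpy(dtype=float), cols


def uncertainty_filter(features: pd.DataFrame, threshold: float = 0.10) -> QcReport:
    """Gate samples on the replicate spread of their response minima.

    For each (sample, sensor) the relative standard deviation (ddof=1) of
    the per-cycle R/R0 minimum is computed across replicate cycles; a
    sample fails if any sensor exceeds ``threshold``. Samples with a single
    replicate pass by default with a warning.
    """
    min_cols = [c for c in features.columns if c.endswith("__minimum")]
    if not min_cols:
        raise ValueError("feature table has no '__minimum' columns")
    rows = []
    failed = set()
    for sample_id, grp in features.groupby("sample_id", sort=True):
        if len(grp) < 2:
            warnings.warn(
                f"sample {sample_id!r} has a single replicate; "
                "uncertainty not assessable, passing by default",
                stacklevel=2,
            )
            for c in min_cols:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "sensor": c.split("__")[0],
                        "rsd": np.nan,
                        "passed": True,
                    }
                )
            continue
        for c in min_cols:
            vals = grp[c].to_numpy(dtype=float)
            rsd = vals.std(ddof=1) / abs(vals.mean())
            ok = rsd <= threshold
            if not ok:
                failed.add(sample_id)
            rows.append(
                {
                    "sample_id": sample_id,
                    "sensor": c.split("__")[0],
                    "rsd": rsd,
                    "passed": ok,
                }
            )
    table = pd.DataFrame(rows, columns=["sample_id", "sensor", "rsd", "passed"])
    all_samples = list(features["sample_id"].drop_duplicates())
    passed = [s for s in all_samples if s not in failed]
    for s in sorted(failed):
        worst = table.loc[table["sample_id"] == s, "rsd"].max()
        logger.info(
            "QC: excluding sample %s (replicate RSD %.1f%% > %.0f%%)",
            s,
            100 * worst,
            100 * threshold,
        )
    return QcReport(
        table=table,
        threshold=threshold,
        passed_samples=passed,
        failed_samples=sorted(failed),
    )


def outlier_mask(
    X: np.ndarray, y: np.ndarray | None = None, k_sigma: float = 3.0
) -> np.ndarray:
    """Flag observations deviating more than ``k_sigma`` within-class
    standard deviations from their class mean in any feature.

    Returns a boolean array, True marking outliers. Features with zero
    within-class variance are ignored; a class degenerate in every feature
    produces no flags and a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    y = np.zeros(n) if y is None else np.asarray(y)
    mask = np.zeros(n, dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        Xc = X[idx]
        if len(idx) < 3:
            raise ValueError(
                f"class {cls!r} has {len(idx)} observations; need >= 3"
            )
        sd = Xc.std(axis=0, ddof=1)
        live = sd > 0
        if not live.any():
            warnings.warn(
                f"class {cls!r} has zero variance in every feature; "
                "no outliers flagged",
                stacklevel=2,
            )
            continue
        z = np.abs(Xc[:, live] - Xc[:, live].mean(axis=0)) / sd[live]
        mask[idx] = (z > k_sigma).any(axis=1)
    return mask


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> list[str]:
    """Rank features by mean impurity-decrease importance of a seeded
    random forest; ties broken by column order (stable sort)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to rank features")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    order = np.argsort(-forest.feature_importances_, kind="stable")
    return [feature_names[i] for i in order]


def _lda(n_components: int) -> LinearDiscriminantAnalysis:
    # eigen solver with a whisper of shrinkage: pooled covariance stays
    # invertible at small n without perturbing well-conditioned problems
    return LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=1e-6, n_components=n_components
    )


def lda_loocv(
    X,
    y,
    n_components: int = 2,
    k_features: int = DEFAULT_K_FEATURES,
    seed: int = 0,
    groups=None,
    feature_names: list[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    selection: str = "in_fold",
) -> LdaResult:
    """Leave-one-out cross-validated LDA with in-fold feature selection.

    Each fold holds out one observation (or one whole group when ``groups``
    is given), re-runs the random-forest ranking and standardization on the
    remaining observations, fits LDA on the top ``k_features`` and predicts
    the held-out fold. ``selection="pre"`` ranks once on the full data
    instead (optimistically biased; provided for comparison only).

    The returned projections come from a full-data fit. A C-class LDA has
    C-1 genuine discriminant axes; if more components are requested, the
    extra axes are principal components of the within-class residuals,
    labelled ``PC*(suppl)``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    classes = sorted(np.unique(y))
    if n <= len(classes):
        raise ValueError("need more observations than classes")
    if k_features > p:
        raise ValueError(f"k_features={k_features} exceeds {p} features")
    if selection not in ("in_fold", "pre"):
        raise ValueError("selection must be 'in_fold' or 'pre'")
    groups = np.arange(n) if groups is None else np.asarray(groups)

    pre_ranked: list[str] | None = None
    if selection == "pre":
        pre_ranked = rank_features(
            X, y, n_trees=n_trees, seed=seed, feature_names=feature_names
        )

    name_to_idx = {f: i for i, f in enumerate(feature_names)}
    preds = np.empty(n, dtype=object)
    for g in np.unique(groups):
        test = groups == g
        train = ~test
        y_tr = y[train]
        if len(np.unique(y_tr)) < len(classes):
            raise ValueError(
                f"fold holding out group {g!r} loses an entire class; "
                "collect more samples per class"
            )
        if k_features >= p:
            chosen = list(feature_names)  # selecting all: ranking is a no-op
        elif selection == "pre":
            chosen = pre_ranked[:k_features]
        else:
            ranked = rank_features(
                X[train],
                y_tr,
                n_trees=n_trees,
                seed=seed,
                feature_names=feature_names,
            )
            chosen = ranked[:k_features]
        idx = [name_to_idx[f] for f in chosen]
        scaler = StandardScaler().fit(X[np.ix_(train, idx)])
        model = _lda(min(n_components, len(classes) - 1, len(idx)))
        model.fit(scaler.transform(X[np.ix_(train, idx)]), y_tr)
        preds[test] = model.predict(scaler.transform(X[np.ix_(test, idx)]))

    cm = confusion_matrix(y, preds.astype(str), labels=classes)
    accuracy = float(np.trace(cm)) / float(cm.sum())

    # full-data fit for the exported projection coordinates
    if k_features >= p:
        full_chosen = list(feature_names)
    else:
        full_chosen = rank_features(
            X, y, n_trees=n_trees, seed=seed, feature_names=feature_names
        )[:k_features]
    fidx = [name_to_idx[f] for f in full_chosen]
    scaler = StandardScaler().fit(X[:, fidx])
    Xs = scaler.transform(X[:, fidx])
    n_genuine = min(n_components, len(classes) - 1, len(fidx))
    model = _lda(n_genuine)
    model.fit(Xs, y)
    coords = model.transform(Xs)[:, :n_genuine]
    axis_names = [f"LD{i + 1}" for i in range(n_genuine)]
    n_extra = n_components - n_genuine
    if n_extra > 0:
        # supplementary axes: PCs of the within-class residuals, so 2-class
        # tasks can still be drawn in 3D without misrepresenting LDA rank
        resid = Xs.copy()
        for cls in classes:
            resid[y == cls] -= Xs[y == cls].mean(axis=0)
        n_extra = min(n_extra, resid.shape[1])
        pca = PCA(n_components=n_extra, random_state=seed).fit(resid)
        coords = np.hstack([coords, pca.transform(resid)])
        axis_names += [f"PC{i + 1}(suppl)" for i in range(n_extra)]

    projections = pd.DataFrame(coords, columns=axis_names)
    projections.insert(0, "label", y)
    confusion = pd.DataFrame(
        cm,
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    return LdaResult(
        projections=projections,
        loocv_predictions=pd.Series(preds.astype(str), name="prediction"),
        confusion=confusion,
        accuracy=accuracy,
        selected_features=full_chosen,
        axis_names=axis_names,
        classes=classes,
    )


def classify_features(
    features: pd.DataFrame,
    task: str,
    flour: str | None = None,
    n_components: int = 2,
    k_features: int = DEFAULT_K_FEATURES,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    qc_threshold: float = 0.10,
    k_sigma: float = 3.0,
    selection: str = "in_fold",
) -> tuple[LdaResult, QcReport, dict]:
    """Run one classification task on a featurized table, with QC.

    ``task="continuous"`` discriminates the three flours on CONTINUOUS
    observations; ``task="prepost"`` discriminates PRE vs POST for one
    flour. Replicates of a sample stay grouped in LOOCV folds.
    """
    if task == "continuous":
        sub = features[features["phase"] == "CONTINUOUS"].copy()
        label_col = "flour"
    elif task == "prepost":
        if flour is None:
            raise ValueError("task 'prepost' requires a flour")
        sub = features[
            (features["flour"] == flour) & (features["phase"].isin(["PRE", "POST"]))
        ].copy()
        label_col = "phase"
    else:
        raise ValueError(f"unknown task {task!r}")
    if sub.empty:
        raise ValueError(f"no observations for task {task!r} (flour={flour!r})")

    n_input = len(sub)
    qc = uncertainty_filter(sub, threshold=qc_threshold)
    sub = sub[sub["sample_id"].isin(qc.passed_samples)].reset_index(drop=True)
    sub = impute_median(sub)
    Xall, cols = _feature_matrix(sub)
    labels = sub[label_col].to_numpy()
    keep = ~outlier_mask(Xall, labels, k_sigma=k_sigma)
    n_outliers = int((~keep).sum())
    sub = sub[keep].reset_index(drop=True)
    X, cols = _feature_matrix(sub)
    result = lda_loocv(
        X,
        sub[label_col].to_numpy(),
        n_components=n_components,
        k_features=k_features,
        seed=seed,
        groups=sub["sample_id"].to_numpy(),
        feature_names=cols,
        n_trees=n_trees,
        selection=selection,
    )
    result.projections.insert(0, "sample_id", sub["sample_id"].to_numpy())
    counts = {
        "observations_in": n_input,
        "samples_failed_qc": qc.n_excluded,
        "observations_after_qc": int(sub.shape[0] + n_outliers),
        "outliers_removed": n_outliers,
        "observations_modelled": int(sub.shape[0]),
    }
    return result, qc, counts


def run_study(config, seed: int | None = None) -> dict:
    """Execute the full study on synthetic data: continuous 3-flour LDA,
    per-flour PRE/POST LDA, and the VOC inventory summary.

    ``config`` is a :class:`doughnose.config.PipelineConfig`; returns a
    JSON-serializable report keyed by stage.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.model_validate(config)
    seed = config.seed if seed is None else seed
    cycle = config.cycle_spec()
    models = config.sensor_models()
    effects = config.class_effects()

    logger.info("simulating %d design cells", len(config.design))
    records = simulate_dataset(
        config.design_tuples(), models=models, effects=effects, cycle=cycle, seed=seed
    )
    n_traces = sum(len(r.traces) for r in records)
    logger.info("featurizing %d traces from %d samples", n_traces, len(records))
    features = featurize_dataset(
        records,
        cycle=cycle,
        sensor_ids=[m.sensor_id for m in models],
        r0_mode=config.preprocessing.r0_mode,
        sg_window_s=config.preprocessing.sg_window_s,
        sg_polyorder=config.preprocessing.sg_polyorder,
        aggregate=config.features.aggregate,
    )

    report: dict = {
        "seed": seed,
        "n_samples": len(records),
        "n_traces": n_traces,
        "n_feature_rows": int(len(features)),
        "analyses": {},
    }
    flours_present = sorted(features["flour"].unique())
    phases_present = set(features["phase"].unique())

    if "CONTINUOUS" in phases_present:
        logger.info("continuous 3-class flour LDA")
        res, qc, counts = classify_features(
            features,
            task="continuous",
            n_components=config.model.n_components_continuous,
            k_features=config.model.k_features,
            seed=seed,
            n_trees=config.model.n_trees,
            qc_threshold=config.model.qc_threshold,
            k_sigma=config.model.k_sigma,
            selection=config.model.selection,
        )
        report["analyses"]["continuous"] = {
            "accuracy": res.accuracy,
            "confusion": res.confusion.to_dict(),
            "selected_features": res.selected_features,
            "axes": res.axis_names,
            "counts": counts,
        }
        report["analyses"]["continuous"]["_result"] = res

    prepost = {}
    for flour in flours_present:
        sub_phases = set(features.loc[features["flour"] == flour, "phase"])
        if not {"PRE", "POST"} <= sub_phases:
            continue
        logger.info("PRE/POST LDA for %s", flour)
        res, qc, counts = classify_features(
            features,
            task="prepost",
            flour=flour,
            n_components=config.model.n_components_prepost,
            k_features=config.model.k_features,
            seed=seed,
            n_trees=config.model.n_trees,
            qc_threshold=config.model.qc_threshold,
            k_sigma=config.model.k_sigma,
            selection=config.model.selection,
        )
        prepost[flour] = {
            "accuracy": res.accuracy,
            "confusion": res.confusion.to_dict(),
            "selected_features": res.selected_features,
            "axes": res.axis_names,
            "counts": counts,
            "_result": res,
        }
    if prepost:
        report["analyses"]["prepost"] = prepost

    logger.info("VOC inventory summary")
    voc_table = simulate_voc_table(
        config.voc.n_common,
        config.voc.n_pre_only,
        config.voc.n_post_only,
        seed=seed,
    )
    summary = voc_inventory.overlap_summary(voc_table)
    report["analyses"]["voc"] = {
        "overlap": summary.as_dict(),
        "class_census": voc_inventory.class_census(voc_table)
        .to_dict(orient="records"),
    }
    report["_features"] = features
    return report
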