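"""Model selection: repeated leave-more-out cross-validation,
classification metrics, latent-variable count selection and VIP-driven
backward elimination.

Cross-validation follows the leave-more-out scheme: each repeat
randomly partitions the samples into 5 disjoint cancellation groups of
~20%, each held out once while the model is trained on the rest; the
whole procedure is repeated many times (default 1000) and metrics are
averaged.  Autoscaling and class-indicator centering are recomputed on
each training fold only, so no information leaks from held-out samples.

Backward elimination wraps the CV engine: at each step the number of
latent variables is re-selected by CV, the cross-validated metrics of
the current variable set are logged, the VIP scores of a full-data fit
rank the variables, and the single lowest-VIP variable is removed.
The procedure runs down to one variable; the returned panel is the
step with the highest mean CV accuracy (ties broken toward fewer
variables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plsda import PLSDAModel, plsda_fit, plsda_predict

__all__ = [
    "CVScheme",
    "ClassificationMetrics",
    "CVSummary",
    "SelectionTrace",
    "classification_metrics",
    "repeated_cv",
    "select_n_lv",
    "backward_eliminate",
]

_EPS = 1e-12


@dataclass
class CVScheme:
    """Leave-more-out scheme: ``n_groups`` cancellation groups of
    ``test_fraction`` of the samples, repeated ``n_repeats`` times."""

    n_groups: int = 5
    test_fraction: float = 0.20
    n_repeats: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if abs(self.n_groups * self.test_fraction - 1.0) > 1e-9:
            raise ValueError(
                "n_groups * test_fraction must equal 1 (full partition per repeat)"
            )
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ClassificationMetrics:
    """Two-class performance summary.

    ``accuracy_pct`` and ``ner_pct`` are percentages; sensitivity,
    specificity and precision are per-class fractions in [0, 1]
    (NaN when undefined, e.g. a class absent from the true labels).
    For balanced classes accuracy and non-error rate coincide.
    """

    accuracy_pct: float
    ner_pct: float
    sensitivity: dict
    specificity: dict
    precision: dict


def _metrics_from_confusion(tp: float, fp: float, tn: float, fn: float) -> ClassificationMetrics:
    total = tp + fp + tn + fn
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    pos, neg = tp + fn, tn + fp
    sens1 = tp / pos if pos else float("nan")  # class 1 recall
    sens0 = tn / neg if neg else float("nan")  # class 0 recall
    ner = 100.0 * np.nanmean([sens0, sens1])
    prec1 = tp / (tp + fp) if (tp + fp) else float("nan")
    prec0 = tn / (tn + fn) if (tn + fn) else float("nan")
    return ClassificationMetrics(
        accuracy_pct=acc,
        ner_pct=float(ner),
        sensitivity={0: sens0, 1: sens1},
        specificity={0: sens1, 1: sens0},  # specificity of one class = recall of the other
        precision={0: prec0, 1: prec1},
    )


def classification_metrics(true_labels, predicted_labels) -> ClassificationMetrics:
    """Accuracy %, non-error rate % and per-class sensitivity /
    specificity / precision from 0/1 label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    tp = float(np.sum((t == 1) & (p == 1)))
    tn = float(np.sum((t == 0) & (p == 0)))
    fp = float(np.sum((t == 0) & (p == 1)))
    fn = float(np.sum((t == 1) & (p == 0)))
    return _metrics_from_confusion(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# CV engine


def _partition(rng: np.random.Generator, units: int, n_groups: int) -> list[np.ndarray]:
    """Random partition into n_groups disjoint groups covering all units;
    remainder distributed one per group, largest groups first."""
    perm = rng.permutation(units)
    base, extra = divmod(units, n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
    out, start = [], 0
    for s in sizes:
        out.append(perm[start : start + s])
        start += s
    return out


def _fit_predict_curve(Xtr, ytr, Xte, max_lv):
    """Train-fold NIPALS with fold-local autoscaling; returns the test
    decision values for every component count 1..A (n_test x A)."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    X = (Xtr - mu) / sd
    Z = (Xte - mu) / sd
    y = np.where(ytr == 1, 1.0, -1.0)
    ym = y.mean()
    yc = y - ym
    n_te = Z.shape[0]
    dec = np.empty((n_te, max_lv))
    pred = np.full(n_te, ym)
    a = 0
    for _ in range(max_lv):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            break
        pl = (X.T @ t) / tt
        q = (yc @ t) / tt
        tz = Z @ w
        pred = pred + q * tz
        dec[:, a] = pred
        X -= np.outer(t, pl)
        Z -= np.outer(tz, pl)
        a += 1
    if a < max_lv:  # covariance exhausted: later components add nothing
        dec[:, a:] = dec[:, a - 1 : a] if a else ym
    return dec


@dataclass
class CVSummary:
    """Aggregate of a repeated leave-more-out run.

    ``metrics`` averages the per-repeat metrics (each repeat pools its
    folds' held-out predictions, which cover every sample exactly
    once); ``accuracy_sd_pct`` is the spread over repeats;
    ``lv_accuracy_curve`` holds the mean CV accuracy for every
    component count up to the one evaluated.
    """

    metrics: ClassificationMetrics
    accuracy_sd_pct: float
    per_repeat_accuracy_pct: np.ndarray
    lv_accuracy_curve: np.ndarray
    n_lv: int
    n_redraws: int = 0


def _repeated_cv_core(
    X: np.ndarray,
    labels: np.ndarray,
    max_lv: int,
    scheme: CVScheme,
    rng: np.random.Generator,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Runs the repeats; returns (per-repeat x per-LV accuracy fractions,
    per-repeat confusion counts [tp, fp, tn, fn] at max_lv, n_redraws)."""
    n = X.shape[0]
    y = np.asarray(labels)
    if groups is not None:
        groups = np.asarray(groups)
        uniq_groups, group_idx = np.unique(groups, return_inverse=True)
        n_units = len(uniq_groups)
    else:
        n_units = n
    acc = np.empty((scheme.n_repeats, max_lv))
    conf = np.empty((scheme.n_repeats, 4))
    redraws = 0
    for rep in range(scheme.n_repeats):
        for attempt in range(101):
            folds_units = _partition(rng, n_units, scheme.n_groups)
            if groups is not None:
                folds = [np.flatnonzero(np.isin(group_idx, fu)) for fu in folds_units]
            else:
                folds = folds_units
            ok = all(np.unique(np.delete(y, f)).size == 2 for f in folds)
            if ok:
                break
            redraws += 1
        else:
            raise RuntimeError("100 consecutive redraws failed to give two-class training folds")
        correct = np.zeros(max_lv)
        tp = fp = tn = fn = 0.0
        for f in folds:
            train = np.setdiff1d(np.arange(n), f, assume_unique=False)
            dec = _fit_predict_curve(X[train], y[train], X[f], max_lv)
            pred = (dec > 0).astype(int)
            correct += (pred == y[f][:, None]).sum(axis=0)
            pf = pred[:, max_lv - 1]
            yf = y[f]
            tp += np.sum((yf == 1) & (pf == 1))
            fp += np.sum((yf == 0) & (pf == 1))
            tn += np.sum((yf == 0) & (pf == 0))
            fn += np.sum((yf == 1) & (pf == 0))
        acc[rep] = correct / n
        conf[rep] = (tp, fp, tn, fn)
    return acc, conf, redraws


def repeated_cv(
    matrix,
    labels,
    n_lv: int,
    scheme: CVScheme,
    groups=None,
) -> CVSummary:
    """Repeated leave-more-out CV of a PLS-DA model with ``n_lv`` LVs.

    ``groups`` (optional) keeps all rows of one biological sample in
    the same cancellation group, for replicate-aware validation.
    Deterministic given ``scheme.seed``.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes coded 0/1")
    rng = np.random.default_rng(np.random.SeedSequence(scheme.seed))
    acc, conf, redraws = _repeated_cv_core(X, y, n_lv, scheme, rng, groups=groups)
    per_repeat = 100.0 * acc[:, n_lv - 1]
    mean_conf = conf.mean(axis=0)
    metrics = _metrics_from_confusion(*mean_conf)
    return CVSummary(
        metrics=metrics,
        accuracy_sd_pct=float(per_repeat.std(ddof=1)) if len(per_repeat) > 1 else 0.0,
        per_repeat_accuracy_pct=per_repeat,
        lv_accuracy_curve=100.0 * acc.mean(axis=0),
        n_lv=n_lv,
        n_redraws=redraws,
    )


def select_n_lv(matrix, labels, scheme: CVScheme, max_lv: int, groups=None) -> int:
    """Latent-variable count with the highest mean CV accuracy
    (evaluated for 1..max_lv in a single CV pass); ties -> fewest LVs."""
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    cap = min(max_lv, n - 1, p)
    if cap < 1:
        raise ValueError("max_lv must allow at least one latent variable")
    summary = repeated_cv(X, labels, cap, scheme, groups=groups)
    curve = summary.lv_accuracy_curve
    return int(np.argmax(np.round(curve, 12))) + 1  # argmax takes first (fewest) on ties


# ---------------------------------------------------------------------------
# Backward elimination


@dataclass
class SelectionTrace:
    """Full log of a VIP backward elimination.

    ``steps`` has one row per elimination step: the variable count and
    LV count of the model evaluated, its mean CV accuracy, the variable
    removed afterwards and that variable's VIP at removal.
    ``selected_set`` is the variable panel of the best step;
    ``final_model`` / ``final_cv`` are a full-data refit and a seeded
    CV re-evaluation of that panel (bitwise reproducible from
    ``selected_step_seed``).
    """

    steps: pd.DataFrame
    selected_set: list
    best_n_lv: int
    best_step: int
    selected_step_seed: int
    final_model: PLSDAModel
    final_cv: CVSummary
    fitting_metrics: ClassificationMetrics

    def write_tsv(self, path) -> None:
        self.steps.to_csv(path, sep="\t", index=False)


def _step_seed(base_seed: int, step: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(step,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def backward_eliminate(
    matrix,
    labels,
    scheme: CVScheme,
    max_lv: int,
    variable_ids=None,
    groups=None,
) -> SelectionTrace:
    """VIP-driven backward elimination of a PLS-DA variable panel.

    At each step the LV count is re-selected by CV (capped at
    ``max_lv``), the step's CV metrics are logged, VIP scores from a
    full-data fit rank the current variables, and the single
    lowest-VIP variable is dropped (VIP ties -> first variable index).
    CV groups are re-randomized at every step from a per-step seed
    derived from ``scheme.seed``, so any step can be replayed exactly.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    if p < 2:
        raise ValueError("backward elimination needs at least 2 variables")
    if variable_ids is None:
        variable_ids = [f"var{i}" for i in range(p)]
    variable_ids = list(variable_ids)

    current = list(range(p))
    rows = []
    step = 0
    while True:
        seed = _step_seed(scheme.seed, step)
        step_scheme = CVScheme(
            n_groups=scheme.n_groups,
            test_fraction=scheme.test_fraction,
            n_repeats=scheme.n_repeats,
            seed=seed,
        )
        Xc = X[:, current]
        cap = min(max_lv, n - 1, len(current))
        summary = repeated_cv(Xc, y, cap, step_scheme, groups=groups)
        curve = summary.lv_accuracy_curve
        n_lv = int(np.argmax(np.round(curve, 12))) + 1
        cv_acc = float(curve[n_lv - 1])

        if len(current) > 1:
            model = plsda_fit(Xc, y, n_lv, scale=True)
            vip = model.vip
            if not np.all(np.isfinite(vip)):
                raise ValueError("non-finite VIP encountered during elimination")
            drop_local = int(np.argmin(vip))  # argmin takes first index on ties
            removed = variable_ids[current[drop_local]]
            removed_vip = float(vip[drop_local])
        else:
            removed, removed_vip = None, float("nan")

        rows.append(
            {
                "step": step,
                "n_vars": len(current),
                "n_lv": n_lv,
                "cv_accuracy_pct": cv_acc,
                "removed": removed,
                "removed_vip": removed_vip,
                "step_seed": seed,
            }
        )
        if len(current) == 1:
            break
        current.pop(drop_local)
        step += 1

    steps = pd.DataFrame(rows)
    # best step: highest CV accuracy; ties -> fewest variables (latest step)
    acc = steps["cv_accuracy_pct"].round(12).to_numpy()
    best_step = int(np.flatnonzero(acc == acc.max())[-1])

    removed_before = steps["removed"].iloc[:best_step].tolist()
    selected_set = [v for v in variable_ids if v not in removed_before]
    best_n_lv = int(steps["n_lv"].iloc[best_step])
    sel_seed = int(steps["step_seed"].iloc[best_step])

    sel_idx = [variable_ids.index(v) for v in selected_set]
    final_model = plsda_fit(X[:, sel_idx], y, best_n_lv, scale=True)
    fit_pred, _, _ = plsda_predict(final_model, X[:, sel_idx])
    fitting = classification_metrics(y, fit_pred)
    final_scheme = CVScheme(scheme.n_groups, scheme.test_fraction, scheme.n_repeats, sel_seed)
    final_cv = repeated_cv(X[:, sel_idx], y, best_n_lv, final_scheme, groups=groups)

    return SelectionTrace(
        steps=steps,
        selected_set=selected_set,
        best_n_lv=best_n_lv,
        best_step=best_step,
        selected_step_seed=sel_seed,
        final_model=final_model,
        final_cv=final_cv,
        fitting_metrics=fitting,
    )
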