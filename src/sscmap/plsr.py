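"""PLSR calibration, cross-validation, latent-variable selection and the
geometry x preprocessing evaluation sweep.

The PLS fit is a NIPALS implementation for a single response, exposing the
weight matrix W, loadings P, response loadings q and the direct score
projection W* = W (P^T W)^-1 used downstream for pixel-score projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import SSCRecord
from .preprocess import PATTERNS, PreprocessSpec, apply_pattern
from .geometry import CORRECTION_MODES


@dataclass
class CalibrationTable:
    """Preprocessed spectra with aligned Brix responses."""

    X: np.ndarray                 # (m, bands)
    y: np.ndarray                 # (m,)
    sample_ids: list[str]
    sections: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y row counts differ")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ValueError("calibration table contains non-finite values")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    def subset(self, rows: np.ndarray) -> "CalibrationTable":
        rows = np.asarray(rows)
        return CalibrationTable(
            X=self.X[rows],
            y=self.y[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            sections=[self.sections[i] for i in rows],
        )


@dataclass
class PLSModel:
    A: int
    W: np.ndarray        # (bands, A) weights
    P: np.ndarray        # (bands, A) loadings
    q: np.ndarray        # (A,) response loadings
    Wstar: np.ndarray    # (bands, A) direct score projection
    x_mean: np.ndarray   # (bands,)
    y_mean: float
    b: np.ndarray        # (bands,) regression vector
    Ttrain: np.ndarray   # (m, A) calibration scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.b + self.y_mean

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.Wstar


def save_model(model: PLSModel, path: str, **metadata) -> None:
    """Serialize a model as a JSON bundle (matrices as nested lists)."""
    import json

    payload = {
        "A": model.A,
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "Wstar": model.Wstar.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "b": model.b.tolist(),
        "Ttrain": model.Ttrain.tolist(),
        "metadata": metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> tuple[PLSModel, dict]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    model = PLSModel(
        A=int(payload["A"]),
        W=np.array(payload["W"]),
        P=np.array(payload["P"]),
        q=np.array(payload["q"]),
        Wstar=np.array(payload["Wstar"]),
        x_mean=np.array(payload["x_mean"]),
        y_mean=float(payload["y_mean"]),
        b=np.array(payload["b"]),
        Ttrain=np.array(payload["Ttrain"]),
    )
    return model, payload.get("metadata", {})


def fit_plsr(table: CalibrationTable, A: int) -> PLSModel:
    """NIPALS PLS1 with mean centering only (no autoscaling)."""
    X = table.X
    y = table.y
    m, n_bands = X.shape
    if A > min(m - 1, n_bands):
        raise ValueError(f"A={A} exceeds attainable rank min(m-1, bands)")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_mean
    ya = y - y_mean

    W = np.zeros((n_bands, A))
    P = np.zeros((n_bands, A))
    q = np.zeros(A)
    T = np.zeros((m, A))
    for a in range(A):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"residual covariance vanished at component {a + 1}; "
                f"attained rank {a}"
            )
        w /= norm
        t = Xa @ w
        tt = t @ t
        if tt < 1e-14:
            raise ValueError(f"degenerate score at component {a + 1}")
        p = Xa.T @ t / tt
        qa = ya @ t / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t

    Wstar = W @ np.linalg.inv(P.T @ W)
    b = Wstar @ q
    return PLSModel(
        A=A, W=W, P=P, q=q, Wstar=Wstar,
        x_mean=x_mean, y_mean=y_mean, b=b, Ttrain=T,
    )


def evaluate(model: PLSModel, X: np.ndarray, y: np.ndarray) -> dict:
    """R^2 and RMSE of model predictions against reference values."""
    y = np.asarray(y, dtype=float)
    pred = model.predict(X)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance reference values; R^2 undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {"R2": r2, "RMSE": rmse}


# ---------------------------------------------------------------------------
# Splitting and cross-validation (fruit-level: both sections stay together)
# ---------------------------------------------------------------------------

def _fruit_means(records: list[SSCRecord]) -> tuple[list[str], np.ndarray]:
    order: list[str] = []
    sums: dict[str, list[float]] = {}
    for r in records:
        if r.sample_id not in sums:
            order.append(r.sample_id)
            sums[r.sample_id] = []
        sums[r.sample_id].append(r.brix)
    means = np.array([np.mean(sums[sid]) for sid in order])
    return order, means


def _brix_bins(means: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin index per fruit; empty bins collapse automatically."""
    n_bins = max(1, min(n_bins, means.size))
    edges = np.quantile(means, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, means, side="right") - 1, 0,
                  len(edges) - 2)
    return idx


def stratified_split(
    records: list[SSCRecord],
    ratio: float = 0.7,
    n_bins: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """SSC-stratified fruit-level train/test split.

    Fruits are binned on mean Brix; each bin contributes ~ratio of its fruits
    to the training side, with the global remainder assigned round-robin so
    the overall train count is round(ratio * n_fruits). Both sections of a
    fruit always land on the same side.
    """
    ids, means = _fruit_means(records)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two fruits to split")
    rng = np.random.default_rng(seed)
    bins = _brix_bins(means, n_bins)
    target_train = int(round(ratio * n))
    train_ids: list[str] = []
    test_pool: list[list[str]] = []
    for b in np.unique(bins):
        members = [ids[i] for i in np.where(bins == b)[0]]
        members = [members[i] for i in rng.permutation(len(members))]
        k = int(np.floor(ratio * len(members)))
        train_ids.extend(members[:k])
        test_pool.append(members[k:])
    # round-robin promotion until the global target is met
    bi = 0
    while len(train_ids) < target_train:
        pool = test_pool[bi % len(test_pool)]
        if pool:
            train_ids.append(pool.pop(0))
        bi += 1
        if all(not p for p in test_pool):
            break
    test_ids = [sid for sid in ids if sid not in set(train_ids)]
    train_ids = [sid for sid in ids if sid in set(train_ids)]  # stable order
    return train_ids, test_ids


def _fold_assignment(
    ids: list[str], means: np.ndarray, folds: int, seed: int
) -> dict[str, int]:
    """Brix-stratified, seeded fold index per fruit."""
    rng = np.random.default_rng(seed)
    order = np.argsort(means, kind="stable")
    # within blocks of similar Brix, shuffle then deal round-robin
    fold_of: dict[str, int] = {}
    dealt = 0
    for start in range(0, len(ids), folds):
        block = order[start:start + folds]
        block = block[rng.permutation(len(block))]
        for j, i in enumerate(block):
            fold_of[ids[i]] = (dealt + j) % folds
        dealt += len(block)
    return fold_of


def cross_validate(
    table: CalibrationTable,
    A_max: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Fruit-level K-fold CV: RMSECV and its standard error per component count.

    SE(A) is the standard deviation of the per-fold RMSE divided by
    sqrt(folds); RMSECV(A) pools all out-of-fold residuals.
    """
    ids = sorted(set(table.sample_ids))
    if len(ids) < folds:
        raise ValueError("fewer fruits than folds")
    fruit_mean = {
        sid: np.mean([table.y[i] for i in range(table.m)
                      if table.sample_ids[i] == sid])
        for sid in ids
    }
    means = np.array([fruit_mean[s] for s in ids])
    fold_of = _fold_assignment(ids, means, folds, seed)
    row_fold = np.array([fold_of[s] for s in table.sample_ids])

    A_max = min(A_max, table.m - int(np.max(np.bincount(row_fold))) - 1,
                table.X.shape[1])
    if A_max < 1:
        raise ValueError("not enough samples for cross-validation")

    sq_resid = np.full((table.m, A_max), np.nan)
    fold_rmse = np.zeros((folds, A_max))
    for f in range(folds):
        val = np.where(row_fold == f)[0]
        trn = np.where(row_fold != f)[0]
        if len(set(table.sample_ids[i] for i in trn)) < 2:
            raise ValueError(f"fold {f} leaves fewer than two training fruits")
        sub = table.subset(trn)
        model = None
        for A in range(1, A_max + 1):
            try:
                model = fit_plsr(sub, A)
            except ValueError:
                if model is None:
                    raise
                # data rank exhausted: curve is flat beyond the attained rank
            pred = model.predict(table.X[val])
            res = table.y[val] - pred
            sq_resid[val, A - 1] = res**2
            fold_rmse[f, A - 1] = np.sqrt(np.mean(res**2))
    rmsecv = np.sqrt(np.nanmean(sq_resid, axis=0))
    se = fold_rmse.std(axis=0, ddof=1) / np.sqrt(folds)
    return {"A": np.arange(1, A_max + 1), "RMSECV": rmsecv, "SE": se}


def select_lv_one_se(cv_curve: dict) -> int:
    """Smallest component count whose RMSECV is within one SE of the minimum."""
    rmsecv = np.asarray(cv_curve["RMSECV"], dtype=float)
    if rmsecv.size == 0:
        raise ValueError("empty cross-validation curve")
    se = np.asarray(cv_curve["SE"], dtype=float)
    a_axis = np.asarray(cv_curve.get("A", np.arange(1, rmsecv.size + 1)))
    i_min = int(np.argmin(rmsecv))
    band = rmsecv[i_min] + se[i_min]
    eligible = np.where(rmsecv <= band)[0]
    return int(a_axis[eligible[0]])


# ---------------------------------------------------------------------------
# The full geometry x preprocessing sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepRecord:
    geometry_mode: str
    pattern: str
    A: int | None = None
    RMSECV: float = np.nan
    RMSEC: float = np.nan
    RMSEP: float = np.nan
    R2cv: float = np.nan
    R2c: float = np.nan
    R2p: float = np.nan
    reliability: float = np.nan
    r_star: float = np.nan
    failure: str | None = None
    d2_cache: list = field(default_factory=list, repr=False)
    manifold: object = field(default=None, repr=False)


def sweep_configurations(
    modes=CORRECTION_MODES, patterns=PATTERNS
) -> list[tuple[str, str]]:
    """The cross product of geometry modes and preprocessing patterns."""
    return [(m, p) for m in modes for p in patterns]


def sweep_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                geometry_mode=r.geometry_mode, pattern=r.pattern, LV=r.A,
                RMSECV=r.RMSECV, RMSEC=r.RMSEC, RMSEP=r.RMSEP,
                R2cv=r.R2cv, R2c=r.R2c, R2p=r.R2p,
                Reliability=r.reliability, r_star=r.r_star,
                failure=r.failure or "",
            )
        )
    return pd.DataFrame(rows)


def run_sweep(
    scenes,
    references: list[SSCRecord],
    modes=CORRECTION_MODES,
    patterns=PATTERNS,
    ratio: float = 0.7,
    folds: int = 5,
    A_max: int = 10,
    k: float = 3.0,
    seed: int = 0,
    roi_preset: str = "preset_linescan",
) -> list[SweepRecord]:
    """Calibrate, select, evaluate and score every (mode, pattern) pair.

    Corrected cubes, flesh ROIs and section spectra are computed once per
    geometry mode and shared across the eight preprocessing patterns.
    """
    from . import imaging, reliability as rel, roi as roi_mod
    from .geometry import correct_cube

    ref_lookup = {(r.sample_id, r.section): r.brix for r in references}
    train_ids, test_ids = stratified_split(references, ratio=ratio, seed=seed)
    folds = min(folds, len(train_ids))  # small batches: at most one fruit per fold
    records: list[SweepRecord] = []

    for mode in modes:
        # per-mode shared stage: correction + ROI + raw section spectra
        per_scene = {}
        for scene in scenes:
            cube = correct_cube(
                scene.cube, scene.dark, scene.white, scene.height,
                scene.geometry_params, mode,
            )
            flesh = roi_mod.flesh_roi(cube, preset=roi_preset)
            sections = roi_mod.section_mean_spectra(
                cube, flesh, sample_id=scene.sample_id
            )
            per_scene[scene.sample_id] = (cube, flesh, sections)

        raw_X, raw_y, raw_ids, raw_secs = [], [], [], []
        for sid, (_, _, sections) in per_scene.items():
            for s in sections:
                key = (sid, s.section)
                if key not in ref_lookup:
                    continue
                raw_X.append(s.spectrum)
                raw_y.append(ref_lookup[key])
                raw_ids.append(sid)
                raw_secs.append(s.section)
        raw_X = np.array(raw_X)
        raw_y = np.array(raw_y)

        for pattern in patterns:
            rec = SweepRecord(geometry_mode=mode, pattern=pattern)
            records.append(rec)
            try:
                spec = PreprocessSpec(pattern=pattern)
                X = apply_pattern(raw_X, spec)
                table = CalibrationTable(
                    X=X, y=raw_y, sample_ids=list(raw_ids),
                    sections=list(raw_secs),
                )
                trn = np.array([i for i in range(table.m)
                                if raw_ids[i] in set(train_ids)])
                tst = np.array([i for i in range(table.m)
                                if raw_ids[i] in set(test_ids)])
                train_tab = table.subset(trn)
                cv = cross_validate(train_tab, A_max=A_max, folds=folds,
                                    seed=seed)
                A = select_lv_one_se(cv)
                model = fit_plsr(train_tab, A)
                cal = evaluate(model, train_tab.X, train_tab.y)
                tst_tab = table.subset(tst)
                prd = evaluate(model, tst_tab.X, tst_tab.y)
                rec.A = A
                rec.RMSECV = float(cv["RMSECV"][A - 1])
                ss_tot = float(np.var(train_tab.y))
                rec.R2cv = 1.0 - rec.RMSECV**2 / ss_tot if ss_tot > 0 else np.nan
                rec.RMSEC, rec.R2c = cal["RMSE"], cal["R2"]
                rec.RMSEP, rec.R2p = prd["RMSE"], prd["R2"]

                manifold = rel.fit_manifold(model.Ttrain, k=k)
                rec.manifold = manifold
                per_sample_rel = []
                imaging_vals, ref_vals = [], []
                for sid in test_ids:
                    cube, flesh, _ = per_scene[sid]
                    ssc_map = imaging.predict_map(cube, flesh, model, spec)
                    result = rel.assess_map(cube, flesh, model, spec, manifold)
                    per_sample_rel.append(result.reliability)
                    rec.d2_cache.append(result.d2)
                    means = imaging.region_imaging_values(ssc_map, flesh.mask)
                    for section in ("top", "bottom"):
                        key = (sid, section)
                        if key in ref_lookup:
                            imaging_vals.append(means[section])
                            ref_vals.append(ref_lookup[key])
                rec.reliability = float(np.mean(per_sample_rel))
                if len(ref_vals) >= 3:
                    rec.r_star = imaging.r_star(imaging_vals, ref_vals)
            except Exception as exc:  # recorded, still counted
                rec.failure = f"{type(exc).__name__}: {exc}"
    return records
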