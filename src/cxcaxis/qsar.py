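"""CoMFA-style 3D-QSAR.

Steric (Lennard-Jones 6-12, sp3-carbon probe) and electrostatic (Coulomb,
+1 probe charge, distance-dependent dielectric eps = r) interaction fields
on a regular lattice around the aligned ligand series, truncated at
±30 kcal/mol; PLS regression of pIC50 on the fields with leave-one-out q²,
training R², an F statistic, repeated random test splits (28% of the series
by default), and coefficient contour extraction.

Classical CoMFA defaults throughout: 1.0 Å grid spacing, 4.0 Å margin,
±30 kcal/mol truncation, at most 5 latent components. Columns with standard
deviation below 0.1 kcal/mol are dropped and the rest mean-centered before
every fit (recomputed per cross-validation fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import LigandRecord

ELEC_CONSTANT = 332.06  # kcal*Å/(mol*e^2)

# Minimal element-typed Lennard-Jones parameters: r_min (Å), epsilon (kcal/mol)
LJ_PARAMS = {
    "H": (1.20, 0.016), "C": (1.70, 0.107), "N": (1.55, 0.095),
    "O": (1.52, 0.116), "S": (1.80, 0.250), "P": (1.80, 0.200),
    "F": (1.47, 0.061), "CL": (1.75, 0.265), "BR": (1.85, 0.320),
    "I": (1.98, 0.400),
}
PROBE_SP3_CARBON = {"r_min": 1.70, "epsilon": 0.107, "charge": 1.0}


@dataclass(frozen=True)
class FieldGrid:
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """Lattice coordinates, x fastest-varying last (C order over dims)."""
        axes = [np.asarray(self.origin)[i] + self.spacing * np.arange(self.dims[i])
                for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def translate(self, shift) -> "FieldGrid":
        return FieldGrid(np.asarray(self.origin) + np.asarray(shift, dtype=float),
                         self.spacing, self.dims)


@dataclass
class FieldMatrix:
    """Per-ligand steric and electrostatic field vectors over the grid."""

    ligand_ids: list[str]
    steric: np.ndarray
    electrostatic: np.ndarray
    grid: FieldGrid
    truncation: float
    mask: np.ndarray | None = None

    def design_matrix(self) -> np.ndarray:
        """Concatenated [steric | electrostatic] block matrix."""
        return np.hstack([self.steric, self.electrostatic])


@dataclass
class SplitSpec:
    test_fraction: float = 0.28
    n_models: int = 10
    seeds: list[int] = field(default_factory=lambda: list(range(1, 11)))

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        if len(self.seeds) != self.n_models:
            raise ValidationError("need one seed per model")


@dataclass
class QSARModel:
    seed: int
    n_components: int
    q2: float
    r2: float
    f_stat: float
    press: float
    train_ids: list[str]
    test_ids: list[str]
    selected: bool
    coefficients: np.ndarray | None = None
    test_r2: float | None = None


def build_grid(ligands, spacing: float = 1.0, margin: float = 4.0) -> FieldGrid:
    """Axis-aligned lattice covering every ligand's bounding box plus margin."""
    coord_sets = []
    for lig in ligands:
        coords = lig.coords if isinstance(lig, LigandRecord) else np.asarray(lig)
        if coords.size:
            coord_sets.append(np.atleast_2d(coords))
    if not coord_sets:
        raise ValidationError("no ligand coordinates")
    allc = np.vstack(coord_sets)
    lo = allc.min(axis=0) - margin
    hi = allc.max(axis=0) + margin
    dims = tuple(int(math.ceil(e / spacing)) + 1 for e in hi - lo)
    return FieldGrid(origin=lo, spacing=float(spacing), dims=dims)


def compute_fields(
    ligand,
    grid: FieldGrid,
    probe: dict = PROBE_SP3_CARBON,
    truncation: float = 30.0,
):
    """Steric and electrostatic probe energies of one ligand on the grid.

    steric  = sum over atoms of eps_ij * ((R_ij/r)^12 - 2 (R_ij/r)^6),
              eps_ij = sqrt(eps_atom * eps_probe), R_ij = r_min_atom + r_min_probe
    elec    = sum over atoms of 332.06 * q_atom * q_probe / r^2   (eps = r)

    Both are clamped to [-truncation, +truncation]; at sterically forbidden
    points (steric at the cap) the electrostatic value is set to the cap and
    flagged in the returned mask.
    """
    if isinstance(ligand, LigandRecord):
        elements, coords, charges = ligand.elements, ligand.coords, ligand.charges
    else:
        elements, coords, charges = ligand
        coords = np.asarray(coords, dtype=float)
        charges = np.asarray(charges, dtype=float)
    params = []
    for el in elements:
        key = str(el).upper()
        if key not in LJ_PARAMS:
            raise ValidationError(f"no Lennard-Jones parameters for element {el!r}")
        params.append(LJ_PARAMS[key])
    r_min = np.array([p[0] for p in params]) + probe["r_min"]
    eps = np.sqrt(np.array([p[1] for p in params]) * probe["epsilon"])

    pts = grid.points()
    diff = pts[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    r = np.maximum(r, 1e-6)
    ratio6 = (r_min[None, :] / r) ** 6
    steric = (eps[None, :] * (ratio6 ** 2 - 2.0 * ratio6)).sum(axis=1)
    elec = (ELEC_CONSTANT * probe["charge"] * charges[None, :] / r ** 2).sum(axis=1)

    mask = steric >= truncation
    steric = np.clip(steric, -truncation, truncation)
    elec = np.clip(elec, -truncation, truncation)
    elec[mask] = truncation
    return steric, elec, mask


def build_field_matrix(
    ligands: list[LigandRecord],
    grid: FieldGrid | None = None,
    spacing: float = 1.0,
    margin: float = 4.0,
    probe: dict = PROBE_SP3_CARBON,
    truncation: float = 30.0,
) -> FieldMatrix:
    """Fields for an aligned ligand series on a shared lattice."""
    if grid is None:
        grid = build_grid(ligands, spacing, margin)
    steric, elec, masks = [], [], []
    for lig in ligands:
        s, e, m = compute_fields(lig, grid, probe, truncation)
        steric.append(s)
        elec.append(e)
        masks.append(m)
    return FieldMatrix(
        ligand_ids=[lig.ligand_id for lig in ligands],
        steric=np.array(steric),
        electrostatic=np.array(elec),
        grid=grid,
        truncation=truncation,
        mask=np.array(masks),
    )


# ---------------------------------------------------------------------------
# PLS with column pretreatment
# ---------------------------------------------------------------------------

@dataclass
class PLSFit:
    n_components: int
    kept_columns: np.ndarray
    x_mean: np.ndarray
    coefficients: np.ndarray   # full-width; zeros on dropped columns
    intercept: float
    r2: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coefficients + self.intercept


def _pretreat(X: np.ndarray, sd_min: float = 0.1) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd >= sd_min)
    if kept.size == 0:
        raise ValidationError("all field columns are near-constant")
    return kept


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int,
            sd_min: float = 0.1) -> PLSFit:
    """PLS1 regression of activity on field columns.

    Near-constant columns (SD < `sd_min`) are dropped and the remainder
    mean-centered; the latent-variable fit itself is the iterative
    NIPALS-type algorithm of scikit-learn's PLSRegression (scale=False).
    """
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValidationError("constant activity vector")
    kept = _pretreat(X, sd_min)
    Xk = X[:, kept]
    n_components = int(min(n_components, len(y) - 1, Xk.shape[1]))
    cross_cov = (Xk - Xk.mean(axis=0)).T @ (y - y.mean())
    if np.abs(cross_cov).max() < 1e-12 * max(1.0, np.abs(Xk).max()):
        # y carries no covariance with any column: the latent direction is
        # undefined and the model reduces to the mean response
        coef_kept = np.zeros(Xk.shape[1])
    else:
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xk, y)
        coef_kept = np.asarray(pls.coef_).reshape(-1)
    coefficients = np.zeros(X.shape[1])
    coefficients[kept] = coef_kept
    x_mean = Xk.mean(axis=0)
    intercept = float(y.mean() - x_mean @ coef_kept)
    pred = X @ coefficients + intercept
    rss = float(((y - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return PLSFit(
        n_components=n_components,
        kept_columns=kept,
        x_mean=x_mean,
        coefficients=coefficients,
        intercept=intercept,
        r2=1.0 - rss / tss,
    )


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int,
           sd_min: float = 0.1) -> tuple[float, float]:
    """Leave-one-out q² = 1 - PRESS/TSS.

    Every held-out sample is predicted by a model refit from scratch on the
    remaining n-1 samples (column filtering and centering recomputed per
    fold); TSS is about the full-sample mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValidationError("leave-one-out needs n >= 3")
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        fit = pls_fit(X[keep], y[keep], n_components, sd_min)
        pred = float(fit.predict(X[i:i + 1])[0])
        press += (y[i] - pred) ** 2
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss, press


def f_statistic(r2: float, n_training: int, n_components: int) -> float:
    """F = (R²/k) / ((1-R²)/(n-k-1)) for a k-component model on n samples."""
    if not 0 <= r2 <= 1:
        raise ValidationError("R² outside [0, 1]")
    if n_training <= n_components + 1:
        raise ValidationError("n_training must exceed n_components + 1")
    if r2 == 1.0:
        return math.inf
    k = n_components
    return (r2 / k) / ((1.0 - r2) / (n_training - k - 1))


def fit_qsar_suite(
    field_matrix: FieldMatrix,
    activities: np.ndarray | dict[str, float],
    split: SplitSpec = None,
    q2_min: float = 0.5,
    r2_min: float = 0.85,
    max_components: int = 5,
    sd_min: float = 0.1,
) -> list[QSARModel]:
    """Repeated random-split model building with LOO component selection.

    Per seed: hold out round(test_fraction * n) ligands, choose the number
    of latent components (1..max_components) maximizing LOO q² on the
    training set, and record q², training R², F and the test ids. Models
    passing q² > `q2_min` and R² >= `r2_min` are flagged selected; the
    returned list is ranked by q² descending.
    """
    split = split or SplitSpec()
    X = field_matrix.design_matrix()
    ids = field_matrix.ligand_ids
    if isinstance(activities, dict):
        missing = [i for i in ids if i not in activities]
        if missing:
            raise ValidationError(f"activities missing for {missing}")
        y = np.array([activities[i] for i in ids], dtype=float)
    else:
        y = np.asarray(activities, dtype=float)
        if len(y) != len(ids):
            raise ValidationError("activity vector length mismatch")
    n = len(ids)
    n_test = int(round(split.test_fraction * n))
    if n - n_test < 6:
        raise ValidationError(
            f"test fraction leaves only {n - n_test} training ligands (< 6)"
        )
    models = []
    for seed in split.seeds:
        rng = np.random.default_rng(seed)
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        best_k, best_q2, best_press = 1, -np.inf, np.nan
        for k in range(1, max_components + 1):
            if k > len(train_idx) - 1:
                break
            q2, press = loo_q2(Xtr, ytr, k, sd_min)
            if q2 > best_q2 + 1e-12:
                best_k, best_q2, best_press = k, q2, press
        fit = pls_fit(Xtr, ytr, best_k, sd_min)
        test_pred = fit.predict(X[test_idx])
        sst = float(((y[test_idx] - ytr.mean()) ** 2).sum())
        test_r2 = 1.0 - float(((y[test_idx] - test_pred) ** 2).sum()) / sst \
            if sst > 0 else float("nan")
        models.append(QSARModel(
            seed=seed,
            n_components=fit.n_components,
            q2=best_q2,
            r2=fit.r2,
            f_stat=f_statistic(max(0.0, min(fit.r2, 1.0)), len(train_idx),
                               fit.n_components),
            press=best_press,
            train_ids=[ids[i] for i in train_idx],
            test_ids=[ids[i] for i in test_idx],
            selected=bool(best_q2 > q2_min and fit.r2 >= r2_min),
            coefficients=fit.coefficients,
            test_r2=test_r2,
        ))
    models.sort(key=lambda m: -m.q2)
    return models


def contour_maps(
    model: QSARModel,
    field_matrix: FieldMatrix,
    upper_pct: float = 80.0,
    lower_pct: float = 20.0,
) -> dict[str, np.ndarray]:
    """Grid points carrying the extreme coefficient*SD products per field.

    Returns coordinates of four point sets: steric +/- and electrostatic
    +/- (the classic green/yellow and blue/red CoMFA contours).
    """
    if model.coefficients is None:
        raise ValidationError("model carries no coefficients")
    n_pts = field_matrix.grid.n_points
    pts = field_matrix.grid.points()
    X = field_matrix.design_matrix()
    sd = X.std(axis=0, ddof=0)
    product = model.coefficients * sd
    out = {}
    for name, block in (("steric", product[:n_pts]),
                        ("electrostatic", product[n_pts:])):
        hi = np.percentile(block, upper_pct)
        lo = np.percentile(block, lower_pct)
        out[f"{name}_positive"] = pts[(block >= hi) & (block > 0)]
        out[f"{name}_negative"] = pts[(block <= lo) & (block < 0)]
    return out
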