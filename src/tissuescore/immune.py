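"""Macrophage and lymphocyte recognition trained from dual-IF ground truth.

Dual-immunofluorescence images (CD68/CD163 for macrophages, CD3/CD20 for
lymphocytes) of the same tissue are co-registered to the brightfield PD-L1
image by blob-centroid point-set alignment (coarse translation from
cross-correlated density maps, refined by iterative closest point).  Cells
matched one-to-one to a marker-positive IF blob inherit the immune label;
those labels train per-task classifiers over the brightfield feature
vector, with model selection by count agreement on a held-out verification
set.  Predicted immune cells keep their PD-L1 bin, so PD-L1 +/- immune
tallies are reportable and the TPS denominator can be immune-corrected.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from .config import FEATURE_COLUMNS, feature_hash
from .synthgen import IF_PANELS, IFPair


class RegistrationError(RuntimeError):
    pass


class FeatureHashError(ValueError):
    pass


@dataclass
class RigidTransform:
    """bf = R(p - center) + center + (dx, dy); rotation in radians."""

    dx: float
    dy: float
    rotation: float
    residual: float = 0.0
    center: tuple = (0.0, 0.0)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        R = np.array([[c, -s], [s, c]])
        ctr = np.asarray(self.center)
        return (np.asarray(pts) - ctr) @ R.T + ctr + np.array([self.dx,
                                                               self.dy])


@dataclass
class ImmuneModel:
    """One trained immune-cell classifier with its selection report."""

    task: str                      # "macrophage" or "lymphocyte"
    classifier: object
    family: str
    feature_hash: str
    selection_report: pd.DataFrame  # family, verification_error
    seed: int

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        if feature_hash() != self.feature_hash:
            raise FeatureHashError(
                "feature order hash mismatch; retrain the model")
        return self.classifier.predict(cells[list(FEATURE_COLUMNS)].to_numpy())


@dataclass
class ImmuneModels:
    macrophage: ImmuneModel
    lymphocyte: ImmuneModel
    subtype: object | None = None   # tissue-vs-alveolar head
    subtype_feature_hash: str = ""

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ImmuneModels":
        return joblib.load(path)


# --------------------------------------------------------------------------
# IF blob detection

def detect_if_blobs(if_pair: IFPair, threshold: float = 0.25,
                    min_area: int = 4) -> pd.DataFrame:
    """Blob centroids per channel: columns x, y, channel, marker."""
    rows = []
    for ci in range(2):
        chan = ndi.gaussian_filter(if_pair.channels[ci].astype(float), 1.0)
        mask = chan > threshold
        labels, n = ndi.label(mask)
        if n == 0:
            continue
        areas = ndi.sum_labels(np.ones_like(chan), labels,
                               index=np.arange(1, n + 1))
        cy, cx = zip(*ndi.center_of_mass(chan, labels,
                                         index=np.arange(1, n + 1)))
        for a, x, y in zip(areas, cx, cy):
            if a >= min_area:
                rows.append((float(x), float(y), ci, if_pair.markers[ci]))
    return pd.DataFrame(rows, columns=["x", "y", "channel", "marker"])


def _dedupe_blobs(blobs: pd.DataFrame, radius: float = 4.0) -> pd.DataFrame:
    """Union across channels: double-positive blobs collapse to one cell."""
    if len(blobs) == 0:
        return blobs.assign(markers=pd.Series([], dtype=object))
    xy = blobs[["x", "y"]].to_numpy()
    tree = cKDTree(xy)
    parent = np.arange(len(blobs))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(radius):
        if blobs.channel.iloc[i] != blobs.channel.iloc[j]:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(len(blobs)):
        groups.setdefault(find(i), []).append(i)
    rows = []
    for members in groups.values():
        sub = blobs.iloc[members]
        rows.append((sub.x.mean(), sub.y.mean(),
                     frozenset(sub.marker)))
    return pd.DataFrame(rows, columns=["x", "y", "markers"])


def count_if_positive_cells(if_pair: IFPair, channel: str = "both",
                            threshold: float = 0.25) -> int:
    """Stain-identified cell count for one channel or the de-duplicated union.

    ``channel`` is a marker name (e.g. "CD68") or "both"; double-positive
    cells in the union count once.
    """
    blobs = detect_if_blobs(if_pair, threshold)
    if channel == "both":
        return len(_dedupe_blobs(blobs))
    if channel not in if_pair.markers:
        raise ValueError(
            f"unknown channel {channel!r}; pair carries {if_pair.markers}")
    return int((blobs.marker == channel).sum())


# --------------------------------------------------------------------------
# registration

def _density_map(xy: np.ndarray, shape, sigma: float = 4.0) -> np.ndarray:
    img = np.zeros(shape)
    ix = np.round(xy).astype(int)
    ok = ((ix[:, 0] >= 0) & (ix[:, 0] < shape[1])
          & (ix[:, 1] >= 0) & (ix[:, 1] < shape[0]))
    np.add.at(img, (ix[ok, 1], ix[ok, 0]), 1.0)
    return ndi.gaussian_filter(img, sigma)


def _kabsch_rigid(src: np.ndarray, dst: np.ndarray):
    """Least-squares rotation+translation mapping src -> dst."""
    sc, dc = src.mean(0), dst.mean(0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = dc - R @ sc
    return R, t


def register_if_to_brightfield(if_pair: IFPair, bf_cells: pd.DataFrame,
                               max_residual: float = 2.0,
                               max_iter: int = 40) -> RigidTransform:
    """Estimate the rigid transform carrying IF coordinates onto brightfield.

    Coarse translation from phase correlation of blob/cell density maps,
    then iterative-closest-point refinement on centroids with a trimmed
    nearest-neighbor match and a Kabsch rigid fit per iteration.
    """
    blobs = _dedupe_blobs(detect_if_blobs(if_pair))
    if len(blobs) < 10:
        raise RegistrationError(
            f"only {len(blobs)} IF blobs detected; need >= 10")
    if_xy = blobs[["x", "y"]].to_numpy()
    bf_xy = bf_cells[["x", "y"]].to_numpy()
    shape = if_pair.channels.shape[1:]

    # coarse translation: plain cross-correlation of Gaussian density maps,
    # restricted to the contract's |offset| < ~10% of the image extent
    F_bf = np.fft.rfft2(_density_map(bf_xy, shape))
    F_if = np.fft.rfft2(_density_map(if_xy, shape))
    corr = np.fft.irfft2(F_bf * np.conj(F_if), s=shape)
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    allowed = (np.abs(fy)[:, None] <= 0.12 * shape[0]) \
        & (np.abs(fx)[None, :] <= 0.12 * shape[1])
    corr = np.where(allowed, corr, -np.inf)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    shift = (fy[iy], fx[ix])
    cur = if_xy + np.array([shift[1], shift[0]])

    tree = cKDTree(bf_xy)
    R_tot = np.eye(2)
    t_tot = np.array([shift[1], shift[0]], dtype=float)
    resid = np.inf
    for _ in range(max_iter):
        dist, idx = tree.query(cur)
        cut = max(6.0, 3.0 * np.median(dist))
        keep = dist < cut
        if keep.sum() < 3:
            break
        R, t = _kabsch_rigid(cur[keep], bf_xy[idx[keep]])
        cur = cur @ R.T + t
        R_tot = R @ R_tot
        t_tot = R @ t_tot + t
        new_resid = float(np.mean(np.linalg.norm(cur[keep]
                                                 - bf_xy[idx[keep]], axis=1)))
        if abs(resid - new_resid) < 1e-6:
            resid = new_resid
            break
        resid = new_resid
    if resid > max_residual:
        raise RegistrationError(
            f"registration did not converge: residual {resid:.2f} px > "
            f"{max_residual} px")

    rotation = math.atan2(R_tot[1, 0], R_tot[0, 0])
    ctr = np.array(if_pair.center)
    # express translation about the image center: bf = R(p-c)+c+t_c
    t_c = R_tot @ ctr + t_tot - ctr
    return RigidTransform(dx=float(t_c[0]), dy=float(t_c[1]),
                          rotation=rotation, residual=resid,
                          center=tuple(ctr))


def match_cells(bf_cells: pd.DataFrame, if_blobs: pd.DataFrame,
                transform: RigidTransform, max_dist: float = 5.0):
    """Mutual-nearest-neighbor pairing of brightfield cells and IF blobs.

    Returns (matches, unmatched_bf, unmatched_if); matches is a DataFrame
    with bf_index / if_index / distance.
    """
    bf_xy = bf_cells[["x", "y"]].to_numpy()
    if len(if_blobs) == 0 or len(bf_cells) == 0:
        return (pd.DataFrame(columns=["bf_index", "if_index", "distance"]),
                list(range(len(bf_cells))), list(range(len(if_blobs))))
    if_xy = transform.apply(if_blobs[["x", "y"]].to_numpy())
    bt = cKDTree(bf_xy)
    it = cKDTree(if_xy)
    d_bi, nn_bi = it.query(bf_xy)          # bf -> nearest if
    d_ib, nn_ib = bt.query(if_xy)          # if -> nearest bf
    rows = []
    for b in range(len(bf_xy)):
        i = nn_bi[b]
        if nn_ib[i] == b and d_bi[b] <= max_dist:
            rows.append((b, int(i), float(d_bi[b])))
    matches = pd.DataFrame(rows, columns=["bf_index", "if_index", "distance"])
    unmatched_bf = sorted(set(range(len(bf_xy))) - set(matches.bf_index))
    unmatched_if = sorted(set(range(len(if_xy))) - set(matches.if_index))
    return matches, unmatched_bf, unmatched_if


def label_from_if(bf_cells: pd.DataFrame, if_blobs: pd.DataFrame,
                  matches: pd.DataFrame, panel: str) -> pd.DataFrame:
    """Transfer IF-derived labels onto brightfield feature rows.

    A cell matched to a blob carrying either panel marker is positive for
    the panel's class; every other cell (unmatched, or matched to a blob of
    foreign markers) is negative.
    """
    if panel not in IF_PANELS:
        raise ValueError(f"unknown panel {panel!r}")
    markers = set(IF_PANELS[panel])
    positive = np.zeros(len(bf_cells), dtype=bool)
    for row in matches.itertuples(index=False):
        blob_markers = if_blobs.markers.iloc[row.if_index]
        if markers & set(blob_markers):
            positive[row.bf_index] = True
    out = bf_cells.copy()
    out["immune_label"] = np.where(positive, panel, f"non-{panel}")
    return out


# --------------------------------------------------------------------------
# model fitting and prediction

def _make_classifier(family: str, seed: int):
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      n_jobs=1)
    if family == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000,
                                                random_state=seed))
    if family == "constant_negative":
        return DummyClassifier(strategy="constant", constant="__negative__")
    raise ValueError(f"unknown classifier family {family!r}")


def fit_immune_model(train: pd.DataFrame, verification: list, task: str,
                     families=("random_forest", "logistic"),
                     seed: int = 0) -> ImmuneModel:
    """Fit candidate families and select by verification count agreement.

    ``train`` must carry an ``immune_label`` column (``task`` vs
    ``non-task``); ``verification`` is a list of (cells DataFrame,
    true_count) pairs with known per-sample counts.  Each candidate is
    scored by the mean absolute percent error between its predicted count
    and the true count; the lowest error wins.  Deterministic given seed.
    """
    if len(families) < 2:
        raise ValueError("need >= 2 candidate families")
    if not verification:
        raise ValueError("empty verification set")
    X = train[list(FEATURE_COLUMNS)].to_numpy()
    y = train.immune_label.to_numpy()
    rows = []
    fitted = {}
    for fam in families:
        clf = _make_classifier(fam, seed)
        if fam == "constant_negative":
            clf.set_params(constant=f"non-{task}")
        clf.fit(X, y)
        errs = []
        for cells, true_count in verification:
            pred = clf.predict(cells[list(FEATURE_COLUMNS)].to_numpy())
            n = int((pred == task).sum())
            errs.append(abs(n - true_count) / max(true_count, 1.0) * 100.0)
        rows.append((fam, float(np.mean(errs))))
        fitted[fam] = clf
    report = pd.DataFrame(rows, columns=["family", "verification_error"])
    best = report.sort_values(["verification_error", "family"],
                              kind="stable").iloc[0]
    return ImmuneModel(task=task, classifier=fitted[best.family],
                       family=str(best.family), feature_hash=feature_hash(),
                       selection_report=report, seed=seed)


def fit_subtype_head(train: pd.DataFrame, seed: int = 0):
    """Tissue-vs-alveolar macrophage head, trained on subtype-labeled rows."""
    from sklearn.ensemble import RandomForestClassifier
    clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    clf.fit(train[list(FEATURE_COLUMNS)].to_numpy(),
            train.subtype_label.to_numpy())
    return clf


def predict_immune_cells(cells: pd.DataFrame, models: ImmuneModels
                         ) -> pd.DataFrame:
    """Set cell_class (tumor / macrophage / lymphocyte / other).

    Macrophages are sub-typed tissue/alveolar when a subtype head is
    present.  The pdl1_bin column is never touched, so PD-L1 +/- immune
    tallies remain consistent with the intensity call.
    """
    out = cells.copy()
    if len(out) == 0:
        return out
    mac = models.macrophage.predict(out) == "macrophage"
    lym = models.lymphocyte.predict(out) == "lymphocyte"
    both = mac & lym
    if both.any():
        pm = _proba(models.macrophage, out, "macrophage")
        pl = _proba(models.lymphocyte, out, "lymphocyte")
        mac = mac & (~both | (pm >= pl))
        lym = lym & (~both | (pl > pm))
    cls = np.where(mac, "macrophage", np.where(lym, "lymphocyte", "other"))
    tumorish = (cls == "other") & (out.compartment == "tumor").to_numpy()
    cls[tumorish] = "tumor"
    out["cell_class"] = cls
    out["macrophage_subtype"] = ""
    if models.subtype is not None and mac.any():
        if models.subtype_feature_hash != feature_hash():
            raise FeatureHashError("subtype head feature hash mismatch")
        sub = models.subtype.predict(
            out.loc[mac, list(FEATURE_COLUMNS)].to_numpy())
        out.loc[mac, "macrophage_subtype"] = sub
    return out


def _proba(model: ImmuneModel, cells: pd.DataFrame, cls: str) -> np.ndarray:
    clf = model.classifier
    X = cells[list(FEATURE_COLUMNS)].to_numpy()
    if hasattr(clf, "predict_proba"):
        classes = list(clf.classes_)
        if cls in classes:
            return clf.predict_proba(X)[:, classes.index(cls)]
    return (clf.predict(X) == cls).astype(float)


def immune_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Counts per (cell_class, compartment, PD-L1 status)."""
    sel = cells[cells.cell_class.isin(("macrophage", "lymphocyte"))].copy()
    sel["pdl1_status"] = np.where(sel.pdl1_bin >= 1, "positive", "negative")
    return (sel.groupby(["cell_class", "compartment", "pdl1_status"])
            .size().rename("count").reset_index())
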