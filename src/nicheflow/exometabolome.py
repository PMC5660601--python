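"""Ion annotation, profile classification, and cross-feeding candidate calling.

An untargeted flow-injection (FIA-TOF) experiment yields one intensity time
series per detected ion across two experimental phases: a *conditioning*
phase in which yeast grows in fresh medium, and a *bacterial* phase in which
the harvested conditioned medium supports LAB growth. A metabolite that is
secreted by yeast and then consumed by bacteria traces a bell-shaped
profile: it accumulates during conditioning and is depleted afterwards.

Ions are classified by two fold changes measured against a pseudo-intensity
floor ε (1% of the table's median positive intensity):

* ``fc_accum``   = (conditioning-phase maximum + ε) / (initial intensity + ε)
* ``fc_deplete`` = (conditioning-phase maximum + ε) / (final intensity + ε)

An ion is *bell* iff both fold changes reach the threshold (default 2,
inclusive), *accumulating* / *depleting* if only one does, otherwise *flat*.
Bell ions annotated against a metabolite reference by accurate mass are the
cross-feeding candidates; unannotated bell ions are reported as unknowns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .masses import ADDUCT_OFFSETS, DEFAULT_ADDUCTS
from .model_io import MetaboliteRef

__all__ = [
    "IonTable",
    "Annotation",
    "ProfileCall",
    "read_ion_table",
    "write_ion_table",
    "annotate_ions",
    "normalize_profiles",
    "phase_fold_changes",
    "classify_profiles",
    "cluster_profiles",
    "select_candidates",
    "differential_secretion",
]

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_DA = 0.005
DEFAULT_FOLD_THRESHOLD = 2.0
ARCHETYPES = ("bell", "accumulating", "depleting", "flat")


@dataclass
class IonTable:
    """Per-ion m/z and intensity series over a two-phase time grid.

    ``intensities`` is an ions × timepoints DataFrame (index: ion_id,
    columns: sampling times in hours, strictly increasing); ``mz`` is a
    Series aligned on ion_id. ``phase_boundary`` (h) separates the yeast
    conditioning phase (t ≤ boundary) from the bacterial phase.
    """

    intensities: pd.DataFrame
    mz: pd.Series
    phase_boundary: float

    def __post_init__(self) -> None:
        tps = np.asarray(self.intensities.columns, dtype=float)
        self.intensities.columns = tps
        if np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (tps[0] <= self.phase_boundary < tps[-1]):
            raise ValueError(
                f"phase boundary {self.phase_boundary} outside time range "
                f"[{tps[0]}, {tps[-1]})"
            )
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        self.intensities.index.name = "ion_id"
        self.mz = self.mz.reindex(self.intensities.index)

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    @property
    def ion_ids(self) -> list[str]:
        return list(self.intensities.index)

    def conditioning_columns(self) -> np.ndarray:
        tps = self.timepoints
        return tps[tps <= self.phase_boundary]

    def epsilon(self) -> float:
        """Pseudo-intensity: 1% of the median positive intensity."""
        vals = self.intensities.to_numpy().ravel()
        pos = vals[vals > 0]
        if pos.size == 0:
            return 1.0
        return 0.01 * float(np.median(pos))

    def scaled(self, factor) -> "IonTable":
        return IonTable(self.intensities.mul(factor), self.mz.copy(), self.phase_boundary)


@dataclass(frozen=True)
class Annotation:
    ion_id: str
    metabolite_id: str
    adduct: str
    mass_error: float  # observed − expected, Da


@dataclass(frozen=True)
class ProfileCall:
    ion_id: str
    archetype: str
    fc_accum: float
    fc_deplete: float
    low_signal: bool = False
    cluster_id: int | None = None


# ---------------------------------------------------------------------------
# TSV I/O


def write_ion_table(table: IonTable, path: str | Path) -> None:
    path = Path(path)
    df = table.intensities.copy()
    df.insert(0, "mz", table.mz)
    cols = ["ion_id", "mz"] + [f"t_{c:g}" for c in table.timepoints]
    out = df.reset_index()
    out.columns = cols
    with open(path, "w") as fh:
        fh.write(f"# phase_boundary_h: {table.phase_boundary:g}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_ion_table(path: str | Path, phase_boundary: float | None = None) -> IonTable:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# phase_boundary_h:"):
            boundary = float(first.split(":", 1)[1])
        else:
            fh.seek(0)
            boundary = None
        df = pd.read_csv(fh, sep="\t")
    if phase_boundary is not None:
        boundary = phase_boundary
    if boundary is None:
        raise ValueError(f"{path}: no phase boundary in file and none supplied")
    df = df.set_index("ion_id")
    mz = df.pop("mz")
    df.columns = [float(c.removeprefix("t_")) for c in df.columns]
    return IonTable(intensities=df, mz=mz, phase_boundary=boundary)


# ---------------------------------------------------------------------------
# annotation


def annotate_ions(
    ions: IonTable,
    reference: list[MetaboliteRef],
    tolerance: float = DEFAULT_TOLERANCE_DA,
    adducts: tuple[str, ...] = DEFAULT_ADDUCTS,
) -> list[Annotation]:
    """Match ion m/z to reference metabolites under the stated adduct rules.

    Every (ion, metabolite, adduct) combination within ``tolerance`` Da is
    reported — accurate-mass annotation is deliberately ambiguous, so one
    ion may receive several annotations and one metabolite several ions.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not reference:
        logger.warning("empty metabolite reference: no annotations possible")
        return []
    for adduct in adducts:
        if adduct not in ADDUCT_OFFSETS:
            raise KeyError(f"unknown adduct {adduct!r}")
    ref_mass = np.array([m.monoisotopic_mass for m in reference])
    out: list[Annotation] = []
    for ion_id, mz in ions.mz.items():
        if not np.isfinite(mz):
            continue
        for adduct in adducts:
            expected = ref_mass + ADDUCT_OFFSETS[adduct]
            err = mz - expected
            for j in np.flatnonzero(np.abs(err) <= tolerance):
                out.append(
                    Annotation(
                        ion_id=str(ion_id),
                        metabolite_id=reference[j].id,
                        adduct=adduct,
                        mass_error=float(err[j]),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_profiles(
    table: IonTable,
    method: str = "none",
    culture_density: pd.Series | None = None,
) -> IonTable:
    """Rescale intensities; profile shapes are preserved (scaling only).

    ``culture-AUC`` divides every intensity by the area under the culture
    density curve on the same time grid (trapezoid rule), expressing
    secretion per unit of cumulative biomass exposure.
    """
    if method == "none":
        return IonTable(table.intensities.copy(), table.mz.copy(), table.phase_boundary)
    if method == "total-intensity":
        total = float(table.intensities.to_numpy().sum())
        if total <= 0:
            raise ValueError("total intensity is zero; cannot normalize")
        return table.scaled(1.0 / total)
    if method == "culture-AUC":
        if culture_density is None:
            raise ValueError("culture-AUC normalization needs a culture density series")
        dens = culture_density.reindex(table.timepoints)
        if dens.isna().any():
            raise ValueError("culture density series does not cover the time grid")
        auc = float(np.trapezoid(dens.to_numpy(), table.timepoints))
        if auc <= 0:
            raise ValueError("culture AUC is zero; cannot normalize")
        return table.scaled(1.0 / auc)
    raise ValueError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# profile classification


def phase_fold_changes(
    series: np.ndarray,
    timepoints: np.ndarray,
    phase_boundary: float,
    epsilon: float,
) -> tuple[float, float, bool]:
    """Accumulation and depletion fold changes of one intensity series.

    The reference peak is the maximum within the conditioning phase
    (boundary inclusive). Returns (fc_accum, fc_deplete, low_signal).
    """
    series = np.asarray(series, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    if series.shape != timepoints.shape:
        raise ValueError("series and time grid differ in length")
    cond = series[timepoints <= phase_boundary]
    low_signal = bool(np.all(series <= 0))
    peak = float(cond.max())
    fc_accum = (peak + epsilon) / (series[0] + epsilon)
    fc_deplete = (peak + epsilon) / (series[-1] + epsilon)
    return float(fc_accum), float(fc_deplete), low_signal


def classify_profiles(
    table: IonTable,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    epsilon: float | None = None,
) -> list[ProfileCall]:
    """Assign each ion an archetype from its two phase fold changes.

    bell ⇔ fc_accum ≥ threshold and fc_deplete ≥ threshold (inclusive);
    accumulating / depleting when only one side passes; flat otherwise.
    Classification is scale-invariant per ion up to the shared ε floor
    (``epsilon``; defaults to 1% of the table's median positive intensity).
    """
    if threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    eps = table.epsilon() if epsilon is None else epsilon
    tps = table.timepoints
    calls = []
    for ion_id, row in table.intensities.iterrows():
        fa, fd, low = phase_fold_changes(row.to_numpy(), tps, table.phase_boundary, eps)
        if fa >= threshold and fd >= threshold:
            arch = "bell"
        elif fa >= threshold:
            arch = "accumulating"
        elif fd >= threshold:
            arch = "depleting"
        else:
            arch = "flat"
        calls.append(
            ProfileCall(ion_id=str(ion_id), archetype=arch, fc_accum=fa,
                        fc_deplete=fd, low_signal=low)
        )
    return calls


def cluster_profiles(table: IonTable, k: int = 4, seed: int = 0) -> pd.Series:
    """k-means on per-ion z-scored profiles; deterministic given seed."""
    n = len(table.intensities)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of ions ({n})")
    X = table.intensities.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if np.unique(Z, axis=0).shape[0] < k:
        warnings.warn(
            "fewer distinct z-scored profiles than clusters; clustering is degenerate",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(Z)
    return pd.Series(labels, index=table.intensities.index, name="cluster_id")


# ---------------------------------------------------------------------------
# candidate selection


def select_candidates(
    calls: list[ProfileCall],
    annotations: list[Annotation],
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-feeding candidates: annotated bell ions, one row per
    (metabolite, ion); unannotated bell ions are returned as unknowns."""
    ann_by_ion: dict[str, list[Annotation]] = {}
    for a in annotations:
        ann_by_ion.setdefault(a.ion_id, []).append(a)
    rows, unknowns = [], []
    for call in calls:
        if call.archetype != "bell":
            continue
        anns = ann_by_ion.get(call.ion_id)
        if not anns:
            unknowns.append(call.ion_id)
            continue
        for a in sorted(anns, key=lambda a: (a.metabolite_id, a.adduct)):
            rows.append(
                {
                    "metabolite": a.metabolite_id,
                    "ion_id": call.ion_id,
                    "adduct": a.adduct,
                    "mass_error": a.mass_error,
                    "fc_accum": call.fc_accum,
                    "fc_deplete": call.fc_deplete,
                }
            )
    cols = ["metabolite", "ion_id", "adduct", "mass_error", "fc_accum", "fc_deplete"]
    df = pd.DataFrame(rows, columns=cols).sort_values(
        ["metabolite", "ion_id"], ignore_index=True
    )
    return df, sorted(unknowns)


# ---------------------------------------------------------------------------
# differential secretion


def differential_secretion(
    control: list[IonTable],
    treated: list[IonTable],
    q_threshold: float = 0.1,
    timepoint: float | None = None,
) -> pd.DataFrame:
    """Per-ion two-sample t-test between replicate arms at end of conditioning.

    Tables should already be culture-AUC normalized. Returns a DataFrame with
    log2 fold change (treated/control), p, BH-adjusted q, and flags. Ions
    with zero variance in both arms get q = 1 and a flag instead of a
    spurious discovery.
    """
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need at least 2 replicates per arm")
    ref = control[0]
    tp = timepoint
    if tp is None:
        cond = ref.conditioning_columns()
        tp = float(cond[-1])

    def arm_matrix(tables):
        return np.column_stack([t.intensities[tp].to_numpy(dtype=float) for t in tables])

    X, Y = arm_matrix(control), arm_matrix(treated)
    eps = ref.epsilon()
    log2fc = np.log2((Y.mean(axis=1) + eps) / (X.mean(axis=1) + eps))
    zero_var = (X.std(axis=1) == 0) & (Y.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(Y, X, axis=1)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fc": log2fc,
            "p": p,
            "q": q,
            "significant": q < q_threshold,
            "zero_variance": zero_var,
        },
        index=ref.intensities.index,
    )
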