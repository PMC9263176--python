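"""Reading, writing and preprocessing of minute-level actigraphy data.

A subject's raw record is a long table of minute-level activity counts
(``subject_id, day_index, minute_of_day, count``), optionally carrying the
three accelerometer axes (medio-lateral ``ml``, antero-posterior ``ap``,
vertical ``vt``) instead of a precomputed count.  Triaxial rows are
combined at read time into the vector-magnitude composite

    VM = sqrt(ML^2 + AP^2 + VT^2).

Records are reshaped into per-subject day x 1440 panels (minutes are
1-based, 1..1440); missing minutes are masked with NaN and never imputed
at this layer.  ``aggregate_to_epochs`` averages panels into diurnal
curves on an epoch grid (144 ten-minute epochs by default), and the module
also houses the versioned JSON serialization used by every fitted-model
artifact plus the long-CSV exports for time-by-distribution objects,
L-moment curves, coefficient surfaces and biomarkers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("sotdr")

MINUTES_PER_DAY = 1440
ARTIFACT_VERSION = "sotdr-artifact-v1"

__all__ = [
    "ActigraphyPanel",
    "StudyTable",
    "vector_magnitude",
    "read_activity_long",
    "write_activity_long",
    "aggregate_to_epochs",
    "epoch_centers_minutes",
    "read_study_table",
    "save_artifact",
    "load_artifact",
    "write_beta_surface_csv",
    "read_beta_surface_csv",
    "write_biomarkers_csv",
]


def vector_magnitude(ml, ap, vt):
    """Triaxial composite ``sqrt(ml^2 + ap^2 + vt^2)``.

    All axes must be finite and nonnegative; works elementwise on arrays.
    """
    arrs = {"ml": np.asarray(ml, float), "ap": np.asarray(ap, float),
            "vt": np.asarray(vt, float)}
    for name, a in arrs.items():
        if np.any(~np.isfinite(a)):
            raise ValueError(f"non-finite value on axis {name!r}")
        if np.any(a < 0):
            raise ValueError(f"negative value on axis {name!r}")
    out = np.sqrt(arrs["ml"] ** 2 + arrs["ap"] ** 2 + arrs["vt"] ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class ActigraphyPanel:
    """Day x minute grid of nonnegative activity for one subject.

    ``values`` has shape (n_days, 1440) with NaN marking missing minutes.
    """

    subject_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != MINUTES_PER_DAY:
            raise ValueError(
                f"panel values must be (n_days, {MINUTES_PER_DAY}), "
                f"got {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ValueError("panel needs at least one day")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("activity values must be nonnegative")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def overall_mean(self) -> float:
        """Subject-specific average activity over all observed minutes."""
        return float(np.nanmean(self.values))

    def diurnal_curve(self) -> np.ndarray:
        """Minute-level diurnal curve: across-day average at each minute."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)


# ---------------------------------------------------------------------------
# long-format activity CSV
# ---------------------------------------------------------------------------

_KEY_COLS = ["subject_id", "day_index", "minute_of_day"]


def read_activity_long(path, drop_missing: bool = True) -> list[ActigraphyPanel]:
    """Read a long-format activity CSV into per-subject panels.

    The file must contain ``subject_id, day_index, minute_of_day`` plus
    either a ``count`` column or the triaxial triple ``ml, ap, vt`` (which
    is converted through :func:`vector_magnitude`; if both are present the
    precomputed count wins and a warning is logged).
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _KEY_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"activity file {path} lacks columns {missing_cols}")
    has_count = "count" in df.columns
    has_axes = all(c in df.columns for c in ("ml", "ap", "vt"))
    if not has_count and not has_axes:
        raise ValueError(
            f"activity file {path} needs a 'count' column or the "
            "triaxial columns ml, ap, vt"
        )
    if has_count and has_axes:
        logger.warning("both count and triaxial columns present; using count")

    bad = df.index[(df["minute_of_day"] < 1) | (df["minute_of_day"] > MINUTES_PER_DAY)]
    if len(bad):
        raise ValueError(
            f"minute_of_day out of range 1..{MINUTES_PER_DAY} at data row "
            f"{int(bad[0]) + 2} of {path}"
        )
    dup = df.duplicated(subset=_KEY_COLS)
    if dup.any():
        row = df.loc[dup, _KEY_COLS].iloc[0]
        raise ValueError(
            "duplicate (subject, day, minute) key "
            f"({row['subject_id']}, {row['day_index']}, {row['minute_of_day']}) "
            f"in {path}"
        )

    if has_count:
        counts = df["count"].to_numpy(float)
    else:
        counts = vector_magnitude(df["ml"], df["ap"], df["vt"])
    nan_mask = np.isnan(counts)
    if nan_mask.any() and not drop_missing:
        raise ValueError("missing counts present and drop_missing is False")
    if np.any(counts[~nan_mask] < 0):
        raise ValueError(f"negative activity count in {path}")
    df = df.assign(_count=counts)

    panels = []
    for sid, grp in df.groupby("subject_id", sort=True):
        days = np.sort(grp["day_index"].unique())
        day_pos = {d: i for i, d in enumerate(days)}
        values = np.full((len(days), MINUTES_PER_DAY), np.nan)
        rows = grp["day_index"].map(day_pos).to_numpy()
        cols = grp["minute_of_day"].to_numpy(int) - 1
        values[rows, cols] = grp["_count"].to_numpy()
        panels.append(ActigraphyPanel(str(sid), values))
    return panels


def write_activity_long(panels: list[ActigraphyPanel], path) -> None:
    """Write panels back to the long CSV format (observed minutes only)."""
    frames = []
    for p in panels:
        days, minutes = np.nonzero(~np.isnan(p.values))
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": p.subject_id,
                    "day_index": days + 1,
                    "minute_of_day": minutes + 1,
                    "count": p.values[days, minutes],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# epoch aggregation
# ---------------------------------------------------------------------------


def epoch_centers_minutes(epoch_minutes: int = 10) -> np.ndarray:
    """Centers of the non-overlapping epochs, in (1-based) minute units.

    The epoch covering minutes 1..10 is labeled by its center 5.5.
    """
    if MINUTES_PER_DAY % epoch_minutes:
        raise ValueError(f"{MINUTES_PER_DAY} not divisible by {epoch_minutes}")
    n = MINUTES_PER_DAY // epoch_minutes
    return 0.5 + epoch_minutes / 2.0 + epoch_minutes * np.arange(n)


def aggregate_to_epochs(panel: ActigraphyPanel, epoch_minutes: int = 10):
    """Diurnal curve on the epoch grid: mean over all non-missing cells.

    Returns ``(centers_minutes, curve)``; an epoch with no observed cells
    is NaN and a warning is logged.
    """
    if MINUTES_PER_DAY % epoch_minutes:
        raise ValueError(f"{MINUTES_PER_DAY} not divisible by {epoch_minutes}")
    n_epochs = MINUTES_PER_DAY // epoch_minutes
    blocks = panel.values.reshape(panel.n_days, n_epochs, epoch_minutes)
    with np.errstate(invalid="ignore"):
        curve = np.nanmean(blocks.reshape(-1, n_epochs, epoch_minutes)
                           .transpose(1, 0, 2).reshape(n_epochs, -1), axis=1)
    if np.isnan(curve).any():
        logger.warning(
            "subject %s: %d epochs with no observations marked missing",
            panel.subject_id, int(np.isnan(curve).sum()),
        )
    return epoch_centers_minutes(epoch_minutes), curve


# ---------------------------------------------------------------------------
# study table: outcomes + covariates
# ---------------------------------------------------------------------------


@dataclass
class StudyTable:
    """One row per subject: outcome, family tag, covariate matrix.

    ``family`` is ``"gaussian"`` (identity link) or ``"binomial"`` (logit).
    """

    subject_ids: list[str]
    y: np.ndarray
    Z: np.ndarray
    family: str
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        if self.Z.size == 0:
            self.Z = np.empty((self.y.size, 0))
        if self.Z.shape[0] != self.y.size:
            raise ValueError("covariate rows do not match outcomes")
        if len(self.subject_ids) != self.y.size:
            raise ValueError("subject_ids do not match outcomes")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("binomial outcomes must be coded 0/1")
        if np.isnan(self.y).any():
            raise ValueError("missing outcomes")
        if np.isnan(self.Z).any():
            raise ValueError("missing covariates; complete cases required")
        if not self.covariate_names:
            self.covariate_names = [f"z{j + 1}" for j in range(self.Z.shape[1])]

    @property
    def n(self) -> int:
        return self.y.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "outcome": self.y,
                           "family": self.family})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.Z[:, j]
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_study_table(path, family: str | None = None) -> StudyTable:
    """Read outcome + covariate CSV (columns: subject_id, outcome,
    optional family, then covariates)."""
    df = pd.read_csv(path)
    for col in ("subject_id", "outcome"):
        if col not in df.columns:
            raise ValueError(f"study table {path} lacks column {col!r}")
    if family is None:
        if "family" not in df.columns:
            raise ValueError("family not given and no 'family' column present")
        fams = df["family"].unique()
        if len(fams) != 1:
            raise ValueError("mixed family tags in study table")
        family = str(fams[0])
    cov_cols = [c for c in df.columns
                if c not in ("subject_id", "outcome", "family")]
    return StudyTable(
        subject_ids=[str(s) for s in df["subject_id"]],
        y=df["outcome"].to_numpy(float),
        Z=df[cov_cols].to_numpy(float) if cov_cols else np.empty((len(df), 0)),
        family=family,
        covariate_names=cov_cols,
    )


# ---------------------------------------------------------------------------
# model artifacts and gridded exports
# ---------------------------------------------------------------------------


def save_artifact(payload: dict, path) -> None:
    """Serialize a fitted-model payload as versioned JSON text."""
    doc = {"version": ARTIFACT_VERSION, **payload}

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(doc, default=_default))


def load_artifact(path, expected_kind: str | None = None) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("version") != ARTIFACT_VERSION:
        raise ValueError(
            f"artifact {path} has version tag {doc.get('version')!r}; "
            f"expected {ARTIFACT_VERSION!r} — refusing to load"
        )
    if expected_kind is not None and doc.get("kind") != expected_kind:
        raise ValueError(
            f"artifact {path} is of kind {doc.get('kind')!r}, "
            f"expected {expected_kind!r}"
        )
    return doc


def write_beta_surface_csv(t_grid, p_grid, surface, path) -> None:
    """Export a coefficient surface as a long (t, p, value) CSV."""
    t_grid = np.asarray(t_grid, float)
    p_grid = np.asarray(p_grid, float)
    surface = np.asarray(surface, float)
    if surface.shape != (t_grid.size, p_grid.size):
        raise ValueError("surface shape does not match grids")
    tt, pp = np.meshgrid(t_grid, p_grid, indexing="ij")
    pd.DataFrame(
        {"t": tt.ravel(), "p": pp.ravel(), "value": surface.ravel()}
    ).to_csv(path, index=False)


def read_beta_surface_csv(path):
    df = pd.read_csv(path)
    t_grid = np.unique(df["t"])
    p_grid = np.unique(df["p"])
    surface = (
        df.pivot(index="t", columns="p", values="value")
        .loc[t_grid, p_grid]
        .to_numpy()
    )
    return t_grid, p_grid, surface


def write_biomarkers_csv(subject_ids, bm: dict, path) -> None:
    """Biomarker table (subject_id, bm_a, bm_T, bm_D, bm_TD)."""
    df = pd.DataFrame({"subject_id": subject_ids})
    for name in ("bm_a", "bm_T", "bm_D", "bm_TD"):
        df[name] = np.asarray(bm[name], float)
    df.to_csv(path, index=False)
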