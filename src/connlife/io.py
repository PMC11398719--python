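"""Loading, validation, and quality control of structural connectomes.

The containers here hold a cohort's behavior table (age, sex, fluid
intelligence) together with per-subject streamline-probability and
streamline-distance matrices over a labeled parcellation.  Quality control
follows the standard connectome pipeline: group-level consistency
thresholding of edges, then subject exclusion for missing behavior,
isolated regions, and extreme connection density.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AGE_SPLIT = 50.0  # years; younger adults below, older adults at/above

VALID_SEX = {"F", "M"}

EXCLUDE_MISSING_BEHAVIOR = "missing_behavior"
EXCLUDE_ZERO_REGION = "zero_connection_region"
EXCLUDE_DENSITY = "density_outlier"


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class Cohort:
    """Behavior table: one row per subject (id, age, sex, fluid intelligence).

    ``group`` is derived: ``YA`` for age < 50 years, ``OA`` otherwise.
    Subjects with missing fluid intelligence are kept but flagged via
    ``has_behavior``; they are removed only by :func:`apply_qc`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "age", "sex", "fluid_intelligence"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)}")
        dupes = t["id"][t["id"].duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate subject ids: {dupes}")
        ages = pd.to_numeric(t["age"], errors="coerce")
        bad = t.loc[ages.isna(), "id"].tolist()
        if bad:
            raise ValueError(f"non-numeric age for subjects: {bad}")
        if (ages <= 0).any():
            bad = t.loc[ages <= 0, "id"].tolist()
            raise ValueError(f"non-positive age for subjects: {bad}")
        bad_sex = sorted(set(t["sex"]) - VALID_SEX)
        if bad_sex:
            raise ValueError(f"sex must be one of {sorted(VALID_SEX)}, got {bad_sex}")
        t = t.copy()
        t["id"] = t["id"].astype(str)
        t["age"] = ages.astype(float)
        t["fluid_intelligence"] = pd.to_numeric(
            t["fluid_intelligence"], errors="coerce"
        )
        t["group"] = np.where(t["age"] < AGE_SPLIT, "YA", "OA")
        t["has_behavior"] = t["fluid_intelligence"].notna()
        self.table = t.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def n(self) -> int:
        return len(self.table)

    def subset(self, ids) -> "Cohort":
        keep = self.table["id"].isin(list(ids))
        return Cohort(self.table.loc[keep].reset_index(drop=True))

    def group_ids(self, group: str) -> list[str]:
        if group == "all":
            return self.ids
        return self.table.loc[self.table["group"] == group, "id"].tolist()


def load_cohort(behavior_table_path) -> Cohort:
    """Read a behavior CSV (columns id, age, sex, fluid_intelligence)."""
    return Cohort(pd.read_csv(behavior_table_path))


# ---------------------------------------------------------------------------
# ConnectomeSet


@dataclass
class ConnectomeSet:
    """Aligned per-subject streamline-probability and distance matrices.

    ``sc`` and ``dist`` are stacked ``(n_subjects, N, N)`` arrays in the
    order of ``ids``.  ``regions`` carries label, hemisphere (L/R) and a
    subcortical flag per region.
    """

    ids: list[str]
    sc: np.ndarray
    dist: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.sc = np.asarray(self.sc, dtype=float)
        self.dist = np.asarray(self.dist, dtype=float)
        s, n, m = self.sc.shape
        if s != len(self.ids):
            raise ValueError("sc stack does not match number of ids")
        if n != m or self.dist.shape != self.sc.shape:
            raise ValueError("matrices must be square and sc/dist shapes equal")
        req = {"label", "hemisphere", "subcortical"}
        if not req <= set(self.regions.columns):
            raise ValueError(f"region metadata needs columns {sorted(req)}")
        if len(self.regions) != n:
            raise ValueError("region metadata length != matrix dimension")

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_regions(self) -> int:
        return self.sc.shape[1]

    def validate(self) -> list[str]:
        """Return a list of diagnostics (empty when clean)."""
        out: list[str] = []
        for name, stack, lo_ok in (("sc", self.sc, 1.0), ("dist", self.dist, None)):
            for sid, m in zip(self.ids, stack):
                if not np.allclose(m, m.T, atol=1e-10):
                    out.append(f"{name}[{sid}]: matrix not symmetric")
                if np.any(np.diag(m) != 0):
                    out.append(f"{name}[{sid}]: nonzero diagonal")
                if np.any(m < 0):
                    out.append(f"{name}[{sid}]: negative entries")
                if lo_ok is not None and np.any(m > lo_ok):
                    out.append(f"{name}[{sid}]: entries above {lo_ok}")
        return out

    def subset(self, ids) -> "ConnectomeSet":
        ids = [str(i) for i in ids]
        pos = {sid: k for k, sid in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return ConnectomeSet(ids, self.sc[idx], self.dist[idx], self.regions)

    def masked(self, mask: np.ndarray) -> "ConnectomeSet":
        """Zero every cell not retained by a boolean edge mask."""
        m = np.asarray(mask, bool)
        return ConnectomeSet(
            list(self.ids), self.sc * m, np.where(m, self.dist, 0.0), self.regions
        )


def load_connectome_set(fixture_dir) -> tuple[ConnectomeSet, Cohort]:
    """Load the on-disk fixture layout.

    Expects ``subjects.csv``, ``regions.csv``, and per-subject headerless
    comma-delimited square matrices under ``sc/<id>.csv`` and
    ``dist/<id>.csv``.
    """
    d = Path(fixture_dir)
    cohort = load_cohort(d / "subjects.csv")
    regions = pd.read_csv(d / "regions.csv")
    sc, dist = [], []
    for sid in cohort.ids:
        for name, acc in (("sc", sc), ("dist", dist)):
            p = d / name / f"{sid}.csv"
            if not p.exists():
                raise FileNotFoundError(f"missing matrix file {p}")
            acc.append(np.loadtxt(p, delimiter=","))
    return ConnectomeSet(cohort.ids, np.stack(sc), np.stack(dist), regions), cohort


# ---------------------------------------------------------------------------
# Density, consistency threshold, QC


def density(matrix: np.ndarray) -> float:
    """Fraction of possible undirected pairs with a nonzero connection."""
    m = np.asarray(matrix)
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.count_nonzero(m[iu]) / len(iu[0]))


def densities(cset: ConnectomeSet) -> np.ndarray:
    return np.array([density(m) for m in cset.sc])


def consistency_mask(cset: ConnectomeSet, min_fraction: float = 0.5) -> np.ndarray:
    """Edges present (sc > 0) in at least ``min_fraction`` of subjects.

    The boundary is inclusive: an edge in exactly half the subjects is
    retained at the default threshold.
    """
    if cset.n_subjects < 1:
        raise ValueError("need at least one subject")
    frac = (cset.sc > 0).mean(axis=0)
    mask = frac >= min_fraction
    np.fill_diagonal(mask, False)
    return mask & mask.T


@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`: who was excluded, and why.

    Densities are computed *after* consistency masking (each subject's
    fraction of retained-edge slots that are nonzero for that subject),
    which is also the basis of the outlier rule.
    """

    density_by_id: dict[str, float]
    density_mean: float
    density_sd: float
    excluded: list[tuple[str, str]]  # (subject id, reason)
    mask: np.ndarray = field(repr=False)
    retained_edge_count: int = 0
    retained_ids: list[str] = field(default_factory=list)
    notes: str = "densities computed after consistency masking"

    def to_dict(self) -> dict:
        return {
            "notes": self.notes,
            "density_mean": self.density_mean,
            "density_sd": self.density_sd,
            "density_by_id": self.density_by_id,
            "excluded": [{"id": i, "reason": r} for i, r in self.excluded],
            "retained_edge_count": int(self.retained_edge_count),
            "retained_ids": self.retained_ids,
        }

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)
        if path is not None:
            Path(path).write_text(s)
        return s

    def log_lines(self) -> list[str]:
        lines = [
            f"QC: {self.notes}",
            f"QC: density mean={self.density_mean:.4f} sd={self.density_sd:.4f}",
            f"QC: retained {len(self.retained_ids)} subjects, "
            f"{self.retained_edge_count} edges",
        ]
        lines += [f"QC: excluded {i} ({r})" for i, r in self.excluded]
        return lines


def apply_qc(
    cset: ConnectomeSet,
    cohort: Cohort,
    sd_threshold: float = 3.0,
    min_fraction: float = 0.5,
) -> tuple[ConnectomeSet, Cohort, QCReport]:
    """Consistency-threshold the edges and exclude unusable subjects.

    Order of operations: (1) apply the group consistency mask; (2) drop
    subjects with missing behavior; (3) drop subjects left with any
    fully disconnected region; (4) a single pass excluding subjects whose
    density lies ``sd_threshold`` SD or more from the mean (inclusive).
    A zero density SD (all subjects identical) excludes no one.
    """
    if cohort.ids != cset.ids:
        cset = cset.subset(cohort.ids)
    mask = consistency_mask(cset, min_fraction)
    masked = cset.masked(mask)

    excluded: list[tuple[str, str]] = []
    remaining = list(masked.ids)

    no_behavior = set(
        cohort.table.loc[~cohort.table["has_behavior"], "id"].tolist()
    )
    for sid in list(remaining):
        if sid in no_behavior:
            excluded.append((sid, EXCLUDE_MISSING_BEHAVIOR))
            remaining.remove(sid)

    pos = {sid: k for k, sid in enumerate(masked.ids)}
    for sid in list(remaining):
        deg = (masked.sc[pos[sid]] > 0).sum(axis=0)
        if np.any(deg == 0):
            excluded.append((sid, EXCLUDE_ZERO_REGION))
            remaining.remove(sid)

    dens = {sid: density(masked.sc[pos[sid]]) for sid in remaining}
    vals = np.array(list(dens.values()))
    # population SD: with the sample SD a single outlier among n subjects
    # can never exceed (n-1)/sqrt(n) SDs (Samuelson's inequality), which
    # would make a 3-SD rule vacuous for small cohorts
    mean = float(vals.mean()) if len(vals) else float("nan")
    sd = float(vals.std()) if len(vals) > 1 else 0.0
    if sd > 0:
        for sid in list(remaining):
            # inclusive boundary ("3 SD or more"), with float slack
            if abs(dens[sid] - mean) >= sd_threshold * sd - 1e-12:
                excluded.append((sid, EXCLUDE_DENSITY))
                remaining.remove(sid)

    if not remaining:
        raise ValueError("QC excluded every subject")

    all_dens = {sid: density(masked.sc[pos[sid]]) for sid in masked.ids}
    report = QCReport(
        density_by_id=all_dens,
        density_mean=mean,
        density_sd=sd,
        excluded=excluded,
        mask=mask,
        retained_edge_count=int(mask[np.triu_indices(masked.n_regions, k=1)].sum()),
        retained_ids=remaining,
    )
    if len(excluded) + len(remaining) != cset.n_subjects:
        raise AssertionError("QC bookkeeping mismatch")
    return masked.subset(remaining), cohort.subset(remaining), report
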