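"""Synthetic lifespan cohorts with known brain-behavior structure.

Real lifespan connectome studies observe ~600 adults aged 18-89 whose
fluid intelligence declines with age (Pearson r near -0.65), with sparse
nonnegative streamline-probability matrices whose weights decay with
inter-region distance and whose short edges are mostly intra-hemispheric.
This module emulates exactly those features and, crucially, *plants*
latent age/cognition-linked components at the edge or region level so
that every downstream stage (QC, efficiency metrics, behavioral PLS,
rolling correlations, regressions) can be tested by recovery against a
known ground truth.

The generative model: regions get random 3D coordinates in two
lateralized blocks; a group template weights each edge proportional to
exp(-distance/lambda), sparsified to a target density; each subject's
weights multiply the template by lognormal noise and by planted
multiplicative effects applied on the log-weight scale (so weights stay
nonnegative).  A single global rescale puts all weights in (0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .io import Cohort, ConnectomeSet

DIST_DECAY_MM = 30.0  # template weight e-folding length
FI_MEAN, FI_SD = 32.0, 6.0  # Cattell-like score scale


@dataclass(frozen=True)
class PlantedEffect:
    """A latent component tied to age and residual cognition.

    ``support`` is a tuple of ``(i, j)`` edge pairs (``edge_set``) or of
    region indices (``region_nodal`` scales all edges incident to the
    region; ``region_local`` scales the edges among the region's template
    neighbors).  Loadings are per-SD multiplicative effects on the
    log-weight scale; negative ``loading_age`` means the component
    weakens with age.
    """

    kind: str  # edge_set | region_nodal | region_local
    support: tuple
    loading_age: float
    loading_fi: float
    hemispheric_bias: str = "none"  # intra | inter | none

    def __post_init__(self):
        if self.kind not in {"edge_set", "region_nodal", "region_local"}:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.hemispheric_bias not in {"intra", "inter", "none"}:
            raise ValueError(f"unknown hemispheric bias {self.hemispheric_bias!r}")
        if len(self.support) == 0:
            raise ValueError("effect support must be non-empty")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study."""

    n_subjects: int = 600
    n_regions: int = 64
    age_range: tuple[float, float] = (18.5, 88.92)
    target_age_fi_corr: float = -0.65
    base_density: float = 0.25
    edge_noise_sd: float = 0.5
    edge_dropout: float = 0.0  # per-subject probability an edge is missed
    fi_noise_sd: float = 1.0
    planted_components: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 6 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 6")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if not -1 < self.target_age_fi_corr < 1:
            raise ValueError("target correlation must be in (-1, 1)")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if self.edge_noise_sd < 0 or self.fi_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0 <= self.edge_dropout < 1:
            raise ValueError("edge_dropout must be in [0, 1)")
        n = self.n_regions
        for eff in self.planted_components:
            if eff.kind == "edge_set":
                for i, j in eff.support:
                    if not (0 <= i < n and 0 <= j < n and i != j):
                        raise ValueError(f"edge ({i},{j}) out of bounds")
            else:
                for r in eff.support:
                    if not 0 <= r < n:
                        raise ValueError(f"region {r} out of bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_components"] = [asdict(e) for e in self.planted_components]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        d["planted_components"] = tuple(
            PlantedEffect(
                kind=e["kind"],
                support=tuple(tuple(s) if isinstance(s, (list, tuple)) else s
                              for s in e["support"]),
                loading_age=e["loading_age"],
                loading_fi=e["loading_fi"],
                hemispheric_bias=e.get("hemispheric_bias", "none"),
            )
            for e in d["planted_components"]
        )
        return cls(**d)


@dataclass
class GroundTruth:
    """What was actually planted, for recovery-based testing."""

    latent_cognition: np.ndarray  # per-subject z of residual cognition
    z_age: np.ndarray
    effects: tuple[PlantedEffect, ...]
    effect_masks: list[np.ndarray]  # boolean (N, N) per effect
    template: np.ndarray
    coords: np.ndarray
    hemisphere: np.ndarray  # 'L'/'R' per region


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Behavior


def generate_behavior(spec: SyntheticSpec) -> Cohort:
    """Ages uniform on the range, balanced sex, FI tied to age.

    Fluid intelligence is ``a * z(age) + fi_noise_sd * z(e)`` with the
    noise exactly orthogonalized against age, so the realized Pearson
    correlation equals ``target_age_fi_corr`` exactly.  With
    ``fi_noise_sd == 0`` the map is noiseless and the correlation is
    ``sign(target)``.
    """
    if spec.n_subjects < 10:
        raise ValueError("need at least 10 subjects to calibrate the correlation")
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_subjects
    ages = rng.uniform(*spec.age_range, size=n)
    sex = rng.choice(["F", "M"], size=n)
    z_age = _zscore(ages)
    e = rng.standard_normal(n)
    e = e - z_age * (e @ z_age) / (z_age @ z_age)
    r, s = spec.target_age_fi_corr, spec.fi_noise_sd
    if s == 0:
        fi_z = np.sign(r) * z_age
    else:
        a = r * s / np.sqrt(1 - r**2)
        fi_z = a * z_age + s * _zscore(e)
    fi = FI_MEAN + FI_SD * _zscore(fi_z)
    table = pd.DataFrame(
        {
            "id": [f"sub-{k:04d}" for k in range(n)],
            "age": ages,
            "sex": sex,
            "fluid_intelligence": fi,
        }
    )
    return Cohort(table)


def latent_cognition(cohort: Cohort) -> np.ndarray:
    """Residual cognition: z-scored FI with the age component removed."""
    z_age = _zscore(cohort.table["age"].to_numpy())
    z_fi = _zscore(cohort.table["fluid_intelligence"].to_numpy(float))
    resid = z_fi - z_age * (z_fi @ z_age) / max(z_age @ z_age, 1e-30)
    return _zscore(resid)


# ---------------------------------------------------------------------------
# Template geometry


def _template(spec: SyntheticSpec):
    """Coordinates, distances, and sparsified group template weights.

    Deterministic given (seed, n_regions, base_density); resamples the
    coordinates up to 10 times if the thresholded template is
    disconnected.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_regions
    half = n // 2
    for attempt in range(10):
        coords = np.empty((n, 3))
        coords[:half, 0] = rng.uniform(-70, -15, half)  # left block
        coords[half:, 0] = rng.uniform(15, 70, half)  # right block
        coords[:, 1] = rng.uniform(-80, 60, n)
        coords[:, 2] = rng.uniform(-50, 70, n)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        w = np.exp(-dist / DIST_DECAY_MM)
        np.fill_diagonal(w, 0.0)
        iu = np.triu_indices(n, k=1)
        m = int(round(spec.base_density * len(iu[0])))
        m = max(m, n - 1)
        # guarantee connectivity: keep the shortest-distance spanning
        # tree, then fill the density quota with the heaviest edges
        mst = minimum_spanning_tree(csr_matrix(dist)).toarray() > 0
        mst = mst | mst.T
        keep = mst[iu].copy()
        order = np.argsort(w[iu])[::-1]
        for idx in order:
            if keep.sum() >= m:
                break
            keep[idx] = True
        mask = np.zeros((n, n), bool)
        mask[iu] = keep
        mask |= mask.T
        template = np.where(mask, w, 0.0)
        ncomp, _ = connected_components(mask, directed=False)
        if ncomp == 1:
            hemi = np.array(["L"] * half + ["R"] * half)
            return coords, dist, template, hemi
        warnings.warn("disconnected template; resampling coordinates")
    raise RuntimeError("could not generate a connected template in 10 attempts")


def template_edges(spec: SyntheticSpec) -> np.ndarray:
    """Upper-triangle (i, j) pairs of the group template, row-major order."""
    _, _, template, _ = _template(spec)
    iu = np.triu_indices(spec.n_regions, k=1)
    present = template[iu] > 0
    return np.column_stack([iu[0][present], iu[1][present]])


def plant_random_edge_component(
    spec: SyntheticSpec,
    n_edges: int,
    loading_age: float,
    loading_fi: float,
    hemispheric_bias: str = "intra",
) -> SyntheticSpec:
    """Append an edge-set effect supported on random template edges.

    ``hemispheric_bias`` restricts the sampled edges to intra- or
    inter-hemispheric template edges (``none`` draws from all).
    """
    edges = template_edges(spec)
    half = spec.n_regions // 2
    same = (edges[:, 0] < half) == (edges[:, 1] < half)
    if hemispheric_bias == "intra":
        pool = edges[same]
    elif hemispheric_bias == "inter":
        pool = edges[~same]
    else:
        pool = edges
    if len(pool) < n_edges:
        raise ValueError(
            f"template has only {len(pool)} {hemispheric_bias} edges, "
            f"need {n_edges}"
        )
    rng = np.random.default_rng([spec.seed, 2, len(spec.planted_components)])
    pick = rng.choice(len(pool), size=n_edges, replace=False)
    support = tuple((int(i), int(j)) for i, j in pool[np.sort(pick)])
    eff = PlantedEffect("edge_set", support, loading_age, loading_fi,
                        hemispheric_bias)
    return replace(spec, planted_components=spec.planted_components + (eff,))


def _effect_edge_mask(eff: PlantedEffect, template: np.ndarray,
                      hemi: np.ndarray) -> np.ndarray:
    """Boolean (N, N) mask of template edges the effect touches."""
    n = template.shape[0]
    mask = np.zeros((n, n), bool)
    adj = template > 0
    if eff.kind == "edge_set":
        for i, j in eff.support:
            mask[i, j] = mask[j, i] = True
    elif eff.kind == "region_nodal":
        for r in eff.support:
            mask[r, :] = mask[:, r] = True
    else:  # region_local: edges among the region's template neighbors
        for r in eff.support:
            nbrs = np.flatnonzero(adj[r])
            mask[np.ix_(nbrs, nbrs)] = True
    if eff.hemispheric_bias != "none":
        same = hemi[:, None] == hemi[None, :]
        mask &= same if eff.hemispheric_bias == "intra" else ~same
    np.fill_diagonal(mask, False)
    mask &= adj
    if not mask.any():
        raise ValueError("effect support does not overlap any template edge")
    return mask


# ---------------------------------------------------------------------------
# Connectomes


def generate_connectomes(
    spec: SyntheticSpec, cohort: Cohort
) -> tuple[ConnectomeSet, GroundTruth]:
    """Per-subject weights = template x lognormal noise x planted effects."""
    coords, dist, template, hemi = _template(spec)
    n = spec.n_regions
    n_sub = cohort.n
    z_age = _zscore(cohort.table["age"].to_numpy())
    z_cog = latent_cognition(cohort)

    masks = [_effect_edge_mask(e, template, hemi) for e in spec.planted_components]

    rng = np.random.default_rng([spec.seed, 3])
    iu = np.triu_indices(n, k=1)
    present = template[iu] > 0
    log_t = np.log(template[iu][present])

    sc = np.zeros((n_sub, n, n))
    for s in range(n_sub):
        logw = log_t + spec.edge_noise_sd * rng.standard_normal(present.sum())
        m = np.zeros((n, n))
        m[iu[0][present], iu[1][present]] = logw
        for eff, mask in zip(spec.planted_components, masks):
            shift = eff.loading_age * z_age[s] + eff.loading_fi * z_cog[s]
            m[mask & (np.triu(np.ones((n, n), bool), 1))] += shift
        w = np.zeros((n, n))
        sel = np.zeros((n, n), bool)
        sel[iu[0][present], iu[1][present]] = True
        w[sel] = np.exp(m[sel])
        if spec.edge_dropout > 0:
            # per-subject missed connections (tractography dropout)
            drop = rng.random(int(present.sum())) < spec.edge_dropout
            w[iu[0][present][drop], iu[1][present][drop]] = 0.0
        sc[s] = w + w.T

    sc /= sc.max()  # single global rescale: weights in (0, 1]
    dist_stack = np.broadcast_to(dist, (n_sub, n, n)).copy()

    regions = pd.DataFrame(
        {
            "id": np.arange(n),
            "label": [f"{h}{k % (n // 2):03d}" for k, h in enumerate(hemi)],
            "hemisphere": hemi,
            "subcortical": [1 if k % (n // 2) >= n // 2 - max(1, n // 20) else 0
                            for k in range(n)],
        }
    )
    cset = ConnectomeSet(cohort.ids, sc, dist_stack, regions)
    gt = GroundTruth(
        latent_cognition=z_cog,
        z_age=z_age,
        effects=spec.planted_components,
        effect_masks=masks,
        template=template,
        coords=coords,
        hemisphere=hemi,
    )
    return cset, gt


def generate_study(spec: SyntheticSpec):
    """Convenience: behavior + connectomes in one call."""
    cohort = generate_behavior(spec)
    cset, gt = generate_connectomes(spec, cohort)
    return cohort, cset, gt


def default_study_spec(seed: int = 0, n_subjects: int = 600,
                       n_regions: int = 64) -> SyntheticSpec:
    """The default study conditions: one age-weakening intra-hemispheric
    edge component whose strength also tracks residual cognition.

    At the default 64 regions the component spans 120 template edges
    (about a quarter of the retained edges); smaller parcellations get a
    proportionally smaller support.
    """
    spec = SyntheticSpec(n_subjects=n_subjects, n_regions=n_regions,
                         edge_dropout=0.05, seed=seed)
    edges = template_edges(spec)
    half = n_regions // 2
    intra = ((edges[:, 0] < half) == (edges[:, 1] < half)).sum()
    n_edges = min(120, max(4, int(intra) // 2))
    return plant_random_edge_component(
        spec, n_edges=n_edges, loading_age=-1.0, loading_fi=0.6,
        hemispheric_bias="intra",
    )


# ---------------------------------------------------------------------------
# Fixture writing


def write_fixture(
    cset: ConnectomeSet,
    cohort: Cohort,
    dir_path,
    spec: SyntheticSpec | None = None,
    overwrite: bool = False,
) -> dict:
    """Write the on-disk fixture layout and return the manifest.

    Layout: ``subjects.csv``, ``regions.csv``, ``sc/<id>.csv`` and
    ``dist/<id>.csv`` (square, headerless, comma-delimited), plus
    ``manifest.json`` recording the spec and seed.  Matrices are written
    with 17 significant digits and round-trip losslessly.
    """
    d = Path(dir_path)
    manifest_path = d / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    (d / "sc").mkdir(parents=True, exist_ok=True)
    (d / "dist").mkdir(parents=True, exist_ok=True)
    cohort.table[["id", "age", "sex", "fluid_intelligence"]].to_csv(
        d / "subjects.csv", index=False
    )
    cset.regions.to_csv(d / "regions.csv", index=False)
    files = ["subjects.csv", "regions.csv"]
    for k, sid in enumerate(cset.ids):
        for name, stack in (("sc", cset.sc), ("dist", cset.dist)):
            rel = f"{name}/{sid}.csv"
            np.savetxt(d / rel, stack[k], delimiter=",", fmt="%.17g")
            files.append(rel)
    manifest = {
        "seed": spec.seed if spec is not None else None,
        "spec": spec.to_dict() if spec is not None else None,
        "n_subjects": cset.n_subjects,
        "n_regions": cset.n_regions,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
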