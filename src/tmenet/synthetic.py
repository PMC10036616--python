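"""Synthetic multiplexed-TMA cohorts with planted multilevel structure.

The generator emulates a two-institution tissue-microarray cohort imaged
with a 7-marker immunofluorescence panel: each patient contributes one or
two circular-core-like images, each image carries a planted three-level
spatial organisation (local phenotypes nested in cellular neighborhoods
nested in tissue areas), and the two patient classes differ in their prior
over tissue-area abundance ("hot", immune-infiltrated versus "cold",
immune-poor architecture).  Ground-truth labels for every level are kept on
the patch grid so downstream recovery can be scored exactly.

Areas are laid out as contiguous Voronoi blobs on the patch grid (seed
labels drawn from the class's area prior), neighborhoods as contiguous
Voronoi sub-blocks within each area, and per-patch phenotypes are sampled
from the neighborhood's phenotype mixture.  Cells are rendered as soft
disks (nucleus on DAPI plus the phenotype's marker expression) over a low
noisy background.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MultiplexedCore, PatientTable, read_core, write_core
from .panel import MarkerPanel, DEFAULT_PANEL


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSpec:
    """Rendering recipe of one planted local phenotype."""

    name: str
    mean_expression: tuple  # length C, arbitrary nonnegative intensity units
    nucleus_radius: float = 3.0  # px
    cell_density: float = 0.006  # cells per px^2... see __post_init__ docnote
    noise_cv: float = 0.25  # coefficient of variation of per-cell expression

    def __post_init__(self):
        expr = np.asarray(self.mean_expression, dtype=float)
        if np.any(expr < 0):
            raise ValueError("mean_expression must be nonnegative")
        if self.nucleus_radius < 1:
            raise ValueError("nucleus_radius must be >= 1 px")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")


@dataclass(frozen=True)
class BatchEffectSpec:
    """Per-institution staining distortion: gain, offset, additive noise."""

    gain: tuple = ()      # per-channel multiplicative gain; empty = all ones
    offset: tuple = ()    # per-channel additive offset; empty = all zeros
    noise_sd: float = 0.0

    def resolve(self, C: int):
        gain = np.ones(C) if len(self.gain) == 0 else np.asarray(self.gain, float)
        offset = (np.zeros(C) if len(self.offset) == 0
                  else np.asarray(self.offset, float))
        if gain.shape != (C,) or offset.shape != (C,):
            raise ValueError(f"batch-effect vectors must have length {C}")
        if np.any(gain <= 0):
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return gain, offset, self.noise_sd


class UnlearnableConfigError(ValueError):
    """Raised when the two classes share identical area priors."""


@dataclass
class CohortConfig:
    """Everything that defines a synthetic cohort draw."""

    n_patients: int = 40
    positive_fraction: float = 0.128  # recurrence prevalence
    cores_per_patient: int = 2
    core_size: int = 512
    patch_size: int = 20
    planted_phenotypes: list = field(default_factory=lambda: default_phenotypes())
    planted_neighborhoods: np.ndarray = None  # (n_neigh, n_phen) mixtures
    planted_areas: np.ndarray = None          # (n_area, n_neigh) mixtures
    area_priors_by_class: np.ndarray = None   # (2, n_area); row 0 = no recurrence
    institutions: list = field(default_factory=lambda: [BatchEffectSpec(),
                                                        BatchEffectSpec()])
    area_seeds_per_core: int = 6
    neighborhood_patches_per_seed: int = 40
    background_level: float = 1.0
    background_sd: float = 0.5
    seed: int = 0
    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self):
        if self.planted_neighborhoods is None:
            self.planted_neighborhoods = default_neighborhoods()
        if self.planted_areas is None:
            self.planted_areas = default_areas()
        if self.area_priors_by_class is None:
            self.area_priors_by_class = default_area_priors()
        self.planted_neighborhoods = np.asarray(self.planted_neighborhoods, float)
        self.planted_areas = np.asarray(self.planted_areas, float)
        self.area_priors_by_class = np.asarray(self.area_priors_by_class, float)
        if self.cores_per_patient not in (1, 2):
            raise ValueError("cores_per_patient must be 1 or 2")
        if self.core_size < self.patch_size:
            raise ValueError("core_size must be >= patch_size")
        for name, m in (("planted_neighborhoods", self.planted_neighborhoods),
                        ("planted_areas", self.planted_areas),
                        ("area_priors_by_class", self.area_priors_by_class)):
            if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name} rows must be probability vectors")
        if self.planted_neighborhoods.shape[1] != len(self.planted_phenotypes):
            raise ValueError("neighborhood mixtures must cover every phenotype")
        if self.planted_areas.shape[1] != self.planted_neighborhoods.shape[0]:
            raise ValueError("area mixtures must cover every neighborhood")
        if self.area_priors_by_class.shape != (2, self.planted_areas.shape[0]):
            raise ValueError("area_priors_by_class must be 2 x n_areas")
        if np.allclose(self.area_priors_by_class[0],
                       self.area_priors_by_class[1]):
            raise UnlearnableConfigError(
                "class area priors are identical for every area; the cohort "
                "carries no class signal")
        for spec in self.planted_phenotypes:
            if len(spec.mean_expression) != self.panel.C:
                raise ValueError(
                    f"phenotype {spec.name} expression length != panel C")

    @property
    def grid(self) -> int:
        return self.core_size // self.patch_size

    @property
    def n_areas(self) -> int:
        return self.planted_areas.shape[0]

    @property
    def n_neighborhoods(self) -> int:
        return self.planted_neighborhoods.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return len(self.planted_phenotypes)


# ---------------------------------------------------------------------------
# Default planted structure: a hot/cold two-class endometrial-like cohort
# ---------------------------------------------------------------------------

def default_phenotypes(panel: MarkerPanel = DEFAULT_PANEL) -> list:
    """Three well-separated phenotypes: tumor (CK+), CD8 T cell, stroma."""
    def expr(**kw):
        v = np.zeros(panel.C)
        for marker, val in kw.items():
            v[panel.index(marker.replace("_", "-"))] = val
        return tuple(v)

    return [
        PhenotypeSpec("tumor", expr(DAPI=60, CK=50, PD_L1=10),
                      nucleus_radius=4.0, cell_density=0.008),
        PhenotypeSpec("cd8_t", expr(DAPI=60, CD8=50, PD_1=15),
                      nucleus_radius=2.5, cell_density=0.010),
        PhenotypeSpec("stroma", expr(DAPI=40, CD68=5),
                      nucleus_radius=3.0, cell_density=0.004),
    ]


def default_neighborhoods() -> np.ndarray:
    # rows: tumor_core, immune_infiltrate; columns: tumor, cd8_t, stroma
    return np.array([[0.80, 0.05, 0.15],
                     [0.30, 0.50, 0.20]])


def default_areas() -> np.ndarray:
    # rows: cold, hot; columns: tumor_core, immune_infiltrate
    return np.array([[0.90, 0.10],
                     [0.20, 0.80]])


def default_area_priors() -> np.ndarray:
    # row 0 = no recurrence ("hot" patients), row 1 = recurrence ("cold")
    # hot-area prior: 0.6 for the hot class vs 0.1 for the cold class
    return np.array([[0.40, 0.60],
                     [0.90, 0.10]])


def two_class_config(n_patients: int = 40, core_size: int = 512,
                     balanced: bool = True, seed: int = 0,
                     cores_per_patient: int = 2,
                     institutions: list | None = None) -> CohortConfig:
    """The planted hot/cold recovery cohort used throughout the test suite."""
    kwargs = {}
    if institutions is not None:
        kwargs["institutions"] = institutions
    return CohortConfig(
        n_patients=n_patients,
        positive_fraction=0.5 if balanced else 0.128,
        cores_per_patient=cores_per_patient,
        core_size=core_size,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGroundTruth:
    """Planted labels for every core on the patch grid, plus cell records."""

    patch_phenotype: dict  # core_id -> (g, g) int array
    patch_neighborhood: dict
    patch_area: dict
    patient_class: dict    # patient_id -> 0/1
    cells: pd.DataFrame    # core_id, y, x, radius, phenotype
    patch_size: int
    phenotype_names: list
    level_sizes: tuple     # (n_phenotypes, n_neighborhoods, n_areas)

    def area_pixel_map(self, core_id: str) -> np.ndarray:
        """Per-pixel area labels (patch-aligned, so exact by construction)."""
        p = self.patch_size
        return np.kron(self.patch_area[core_id], np.ones((p, p), dtype=int))

    def flat_labels(self, level: str, core_order: list) -> np.ndarray:
        maps = {"phenotype": self.patch_phenotype,
                "neighborhood": self.patch_neighborhood,
                "area": self.patch_area}[level]
        return np.concatenate([maps[cid].ravel() for cid in core_order])

    def class_area_fractions(self) -> pd.DataFrame:
        """Mean ground-truth area fraction per patient class."""
        rows = []
        core_pid = {cid: cid.rsplit("_", 1)[0] for cid in self.patch_area}
        n_areas = self.level_sizes[2]
        for cid, amap in self.patch_area.items():
            pid = core_pid[cid]
            frac = np.bincount(amap.ravel(), minlength=n_areas) / amap.size
            rows.append({"patient_id": pid,
                         "label": self.patient_class[pid],
                         **{f"area_{a}": frac[a] for a in range(n_areas)}})
        df = pd.DataFrame(rows)
        return df.groupby("label").mean(numeric_only=True)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _voronoi_labels(grid: int, seeds_yx: np.ndarray, seed_labels: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Nearest-seed label for every patch-grid cell (within ``mask``)."""
    yy, xx = np.mgrid[0:grid, 0:grid]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    d2 = ((pts[:, None, :] - seeds_yx[None, :, :]) ** 2).sum(axis=2)
    lab = seed_labels[np.argmin(d2, axis=1)].reshape(grid, grid)
    if mask is not None:
        lab = np.where(mask, lab, -1)
    return lab


def _render_core(shape_hw: tuple, cells: list, config: CohortConfig,
                 rng: np.random.Generator) -> np.ndarray:
    h, w = shape_hw
    C = config.panel.C
    img = np.empty((h, w, C), dtype=np.float32)
    img[:] = config.background_level
    if config.background_sd > 0:
        img += rng.normal(0.0, config.background_sd,
                          size=img.shape).astype(np.float32)
    np.clip(img, 0.0, None, out=img)
    for (cy, cx, radius, expr) in cells:
        r = int(np.ceil(radius))
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = np.clip(1.0 - d2 / radius ** 2, 0.0, None)
        img[y0:y1, x0:x1, :] += disk[:, :, None] * expr[None, None, :]
    return img


def apply_batch_effect(core: MultiplexedCore, spec: BatchEffectSpec,
                       seed: int = 0) -> MultiplexedCore:
    """Distort a core's intensities: ``gain * x + offset + noise``, clipped at 0.

    Ground-truth labels are untouched; only pixel intensities change.  An
    identity spec (unit gain, zero offset, zero noise) returns pixels equal
    to the input.
    """
    gain, offset, noise_sd = spec.resolve(core.panel.C)
    rng = np.random.default_rng(seed)
    out = core.pixels.astype(np.float64) * gain + offset
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    out = np.clip(out, 0.0, None)
    return MultiplexedCore(pixels=out.astype(np.float32), core_id=core.core_id,
                           patient_id=core.patient_id,
                           institution_id=core.institution_id,
                           panel=core.panel)


def generate_cohort(config: CohortConfig, render_images: bool = True):
    """Draw one synthetic cohort.

    Returns ``(cores, patient_table, ground_truth)``.  Deterministic for a
    fixed config seed.  With ``render_images=False`` only the ground-truth
    labels and patient table are produced (``cores`` is an empty list) —
    useful when a test needs planted labels but no pixels.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_patients
    n_pos = int(round(n * config.positive_fraction))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    grid = config.grid
    p = config.patch_size
    side = grid * p  # rendered region; border remainders carry background only
    n_inst = max(1, len(config.institutions))

    cores: list[MultiplexedCore] = []
    gt_phen, gt_neigh, gt_area = {}, {}, {}
    patient_class = {}
    cell_rows = []
    table_rows = []
    core_seeds = ss.spawn(n * config.cores_per_patient)
    patient_seeds = ss.spawn(n)

    dirichlet_conc = 20.0  # per-core area fractions concentrate on the prior

    for i in range(n):
        pid = f"pt{i:03d}"
        label = int(labels[i])
        inst = i % n_inst
        patient_class[pid] = label
        prior = config.area_priors_by_class[label]
        core_ids = []
        cold_frac_acc = []
        for j in range(config.cores_per_patient):
            cid = f"{pid}_{j}"
            core_ids.append(cid)
            crng = np.random.default_rng(core_seeds[i * config.cores_per_patient + j])

            # --- area blobs: Voronoi with prior-labelled seeds ----------
            n_seeds = config.area_seeds_per_core
            seeds_yx = crng.uniform(0, grid, size=(n_seeds, 2))
            seed_labels = crng.choice(config.n_areas, size=n_seeds, p=prior)
            area_map = _voronoi_labels(grid, seeds_yx, seed_labels)

            # --- neighborhoods: contiguous blocks within each area ------
            neigh_map = np.full((grid, grid), -1, dtype=int)
            for a in range(config.n_areas):
                mask = area_map == a
                count = int(mask.sum())
                if count == 0:
                    continue
                k = max(1, count // config.neighborhood_patches_per_seed)
                cells_yx = np.argwhere(mask).astype(float)
                pick = crng.choice(count, size=k, replace=False)
                sub_seeds = cells_yx[pick] + crng.uniform(-0.25, 0.25, size=(k, 2))
                sub_labels = crng.choice(config.n_neighborhoods, size=k,
                                         p=config.planted_areas[a])
                d2 = ((cells_yx[:, None, :] - sub_seeds[None, :, :]) ** 2).sum(axis=2)
                neigh_map[mask] = sub_labels[np.argmin(d2, axis=1)]

            # --- phenotypes: per-patch draw from neighborhood mixture ---
            phen_map = np.empty((grid, grid), dtype=int)
            flat_neigh = neigh_map.ravel()
            flat_phen = phen_map.ravel()
            for nb in range(config.n_neighborhoods):
                sel = flat_neigh == nb
                flat_phen[sel] = crng.choice(config.n_phenotypes,
                                             size=int(sel.sum()),
                                             p=config.planted_neighborhoods[nb])
            phen_map = flat_phen.reshape(grid, grid)

            gt_area[cid] = area_map
            gt_neigh[cid] = neigh_map
            gt_phen[cid] = phen_map
            cold_frac_acc.append(float(np.mean(area_map == 0)))

            # --- cell placement and rendering ---------------------------
            cells = []
            for (gy, gx), phen_idx in np.ndenumerate(phen_map):
                spec = config.planted_phenotypes[phen_idx]
                lam = spec.cell_density * p * p
                n_cells = crng.poisson(lam)
                for _ in range(n_cells):
                    cy = gy * p + crng.uniform(0, p)
                    cx = gx * p + crng.uniform(0, p)
                    radius = spec.nucleus_radius * crng.uniform(0.8, 1.2)
                    expr = np.asarray(spec.mean_expression, float)
                    if spec.noise_cv > 0:
                        shape = 1.0 / spec.noise_cv ** 2
                        expr = expr * crng.gamma(shape, 1.0 / shape,
                                                 size=expr.shape)
                    cells.append((cy, cx, radius, expr))
                    cell_rows.append({"core_id": cid, "y": cy, "x": cx,
                                      "radius": radius,
                                      "phenotype": phen_idx})
            if render_images:
                pixels = _render_core((config.core_size, config.core_size),
                                      cells, config, crng)
                core = MultiplexedCore(pixels=pixels, core_id=cid,
                                       patient_id=pid,
                                       institution_id=f"inst{inst}",
                                       panel=config.panel)
                if config.institutions:
                    eff_seed = int(crng.integers(0, 2 ** 31 - 1))
                    core = apply_batch_effect(
                        core, config.institutions[inst], seed=eff_seed)
                cores.append(core)

        # --- covariates: FIGO weakly tracks cold-area fraction ----------
        cold_frac = float(np.mean(cold_frac_acc))
        prng = np.random.default_rng(patient_seeds[i])
        figo = 1 + prng.binomial(3, np.clip(0.10 + 0.35 * cold_frac, 0, 1))
        table_rows.append({
            "patient_id": pid,
            "label": label,
            "institution": f"inst{inst}",
            "core_ids": ";".join(core_ids),
            "figo_stage": int(figo),
            "grade": int(1 + prng.binomial(1, 0.3)),
            "age": float(np.round(prng.normal(64.5, 10.0), 1)),
            "lvi": int(prng.binomial(1, 0.15)),
            "mmrp_deficient": int(prng.binomial(1, 0.18)),
            "pole_mutated": int(prng.binomial(1, 0.032)),
            "p53_abnormal": int(prng.binomial(1, 0.032)),
        })

    table = PatientTable(pd.DataFrame(table_rows),
                         max_cores=config.cores_per_patient)
    cells_df = pd.DataFrame(cell_rows,
                            columns=["core_id", "y", "x", "radius", "phenotype"])
    gt = SyntheticGroundTruth(
        patch_phenotype=gt_phen, patch_neighborhood=gt_neigh,
        patch_area=gt_area, patient_class=patient_class, cells=cells_df,
        patch_size=p,
        phenotype_names=[s.name for s in config.planted_phenotypes],
        level_sizes=(config.n_phenotypes, config.n_neighborhoods,
                     config.n_areas))
    return cores, table, gt


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort, directory) -> dict:
    """Write cores (multipage TIFF), patient table, and ground truth.

    Returns the manifest (also written as ``manifest.json``): every file
    with its sha256 checksum.  Read-back via :func:`read_cohort`
    round-trips pixel arrays bit-exactly.
    """
    cores, table, gt = cohort
    directory = Path(directory)
    (directory / "cores").mkdir(parents=True, exist_ok=True)
    files = {}
    for core in cores:
        rel = f"cores/{core.core_id}.tif"
        write_core(core, directory / rel)
        files[rel] = _sha256(directory / rel)

    table.to_csv(directory / "patients.csv")
    files["patients.csv"] = _sha256(directory / "patients.csv")

    rows = []
    for cid in sorted(gt.patch_area):
        g = gt.patch_area[cid].shape[0]
        for r in range(g):
            for c in range(g):
                rows.append((cid, r, c, gt.patch_phenotype[cid][r, c],
                             gt.patch_neighborhood[cid][r, c],
                             gt.patch_area[cid][r, c]))
    pd.DataFrame(rows, columns=["core_id", "patch_row", "patch_col",
                                "phenotype", "neighborhood", "area"]
                 ).to_csv(directory / "ground_truth_patches.csv", index=False)
    files["ground_truth_patches.csv"] = _sha256(
        directory / "ground_truth_patches.csv")

    gt.cells.to_csv(directory / "ground_truth_cells.csv", index=False)
    files["ground_truth_cells.csv"] = _sha256(
        directory / "ground_truth_cells.csv")

    meta = {"patch_size": gt.patch_size,
            "phenotype_names": gt.phenotype_names,
            "level_sizes": list(gt.level_sizes)}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    files["meta.json"] = _sha256(directory / "meta.json")

    manifest = {"files": files, "n_cores": len(cores),
                "n_patients": len(table.patient_ids)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort(directory, panel: MarkerPanel = DEFAULT_PANEL):
    """Inverse of :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    table = PatientTable.from_csv(directory / "patients.csv")
    pid_of = {}
    inst_of = {}
    for _, row in table.frame.iterrows():
        for cid in str(row["core_ids"]).split(";"):
            pid_of[cid] = row["patient_id"]
            inst_of[cid] = row["institution"]
    cores = []
    for rel in sorted(f for f in manifest["files"] if f.startswith("cores/")):
        cid = Path(rel).stem
        cores.append(read_core(directory / rel, panel, core_id=cid,
                               patient_id=pid_of.get(cid, ""),
                               institution_id=inst_of.get(cid, "inst0")))
    gtp = pd.read_csv(directory / "ground_truth_patches.csv")
    meta = json.loads((directory / "meta.json").read_text())
    phen, neigh, area = {}, {}, {}
    for cid, sub in gtp.groupby("core_id"):
        g = int(sub["patch_row"].max()) + 1
        for name, store in (("phenotype", phen), ("neighborhood", neigh),
                            ("area", area)):
            m = np.zeros((g, g), dtype=int)
            m[sub["patch_row"], sub["patch_col"]] = sub[name]
            store[cid] = m
    cells = pd.read_csv(directory / "ground_truth_cells.csv")
    patient_class = dict(zip(table.frame["patient_id"],
                             table.frame["label"].astype(int)))
    gt = SyntheticGroundTruth(patch_phenotype=phen, patch_neighborhood=neigh,
                              patch_area=area, patient_class=patient_class,
                              cells=cells, patch_size=int(meta["patch_size"]),
                              phenotype_names=list(meta["phenotype_names"]),
                              level_sizes=tuple(meta["level_sizes"]))
    return cores, table, gt
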