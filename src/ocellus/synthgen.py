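"""Synthetic specimen datasets and trees with known ground truth.

The generator emulates the statistical structure the analyses assume,
so every downstream stage can be tested against known truth:

* a pure-birth (Yule) species tree scaled to unit root depth;
* negative allometry of eye size against body size: eye diameter =
  a * SL^b with b in (0, 1), where log a carries Brownian species
  effects on the tree;
* an eyespot whose area matches the eye's area (isometric, zero
  intercept) and an eyespot "pupil" that exceeds the real pupil by a
  constant area offset (slope one, positive intercept) sized so the
  eyespot pupil is about four times the real pupil at the size where
  eyespots first appear;
* a per-individual ontogenetic size window of eyespot presence: each
  fish draws a gain threshold (~20 mm SL) and a loss threshold
  (~80 mm SL) and carries an eyespot while its length lies between
  them.  Morphometrics exist only for eyespot-bearing specimens.

Features are modelled as ellipses: the recorded diameter is the maximum
diameter and the recorded area carries an axis-ratio factor, so every
generated record satisfies the data model's geometry invariants by
construction (a handful of extreme draws are clipped to keep nested
features nested).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .datamodel import Dataset, MorphometricRecord, SpecimenRecord, write_specimens
from .treekit import Phylogeny

__all__ = ["GeneratorConfig", "simulate_tree", "simulate_dataset", "write_simulation"]

#: Range of ellipse axis ratios (minor/major) for digitized features.
AXIS_RATIO_RANGE = (0.85, 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic specimen generator.

    Defaults encode the anchors the analyses are designed around: eyespot
    area matching eye area, an eyespot pupil four times the real pupil
    (at the acquisition size), eyespot gain near 20 mm SL and loss
    centred on 80 mm SL.
    """

    n_species: int = 150
    specimens_per_species: tuple[int, int] = (2, 12)
    sl_range_mm: tuple[float, float] = (10.0, 200.0)
    sl_median_mm: float = 80.0
    sl_log_sd: float = 0.55
    allometry_coef: float = 0.4
    allometry_exp: float = 0.8
    pupil_fraction: float = 0.45
    eyespot_area_ratio: float = 1.0
    eyespot_pupil_area_ratio: float = 4.0
    gain_mean_mm: float = 20.0
    gain_sd_mm: float = 5.0
    loss_mean_mm: float = 80.0
    loss_sd_mm: float = 15.0
    bm_sigma: float = 0.1
    measurement_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        lo, hi = self.specimens_per_species
        if not (1 <= lo <= hi):
            raise ValueError("specimens_per_species must be an increasing range >= 1")
        if not (0 < self.sl_range_mm[0] < self.sl_range_mm[1]):
            raise ValueError("sl_range_mm must be an increasing positive interval")
        if not (self.sl_range_mm[0] <= self.sl_median_mm <= self.sl_range_mm[1]):
            raise ValueError("sl_median_mm must lie inside sl_range_mm")
        if self.sl_log_sd <= 0:
            raise ValueError("sl_log_sd must be positive")
        if not 0 < self.allometry_exp < 1:
            raise ValueError("allometry_exp must lie in (0, 1): negative allometry")
        if not 0 < self.pupil_fraction < 1:
            raise ValueError("pupil_fraction must lie in (0, 1)")
        if self.gain_mean_mm >= self.loss_mean_mm:
            raise ValueError("gain_mean_mm must be below loss_mean_mm")
        for name in (
            "allometry_coef",
            "eyespot_area_ratio",
            "eyespot_pupil_area_ratio",
            "gain_sd_mm",
            "loss_sd_mm",
            "bm_sigma",
            "measurement_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def eyespot_pupil_offset_mm2(self) -> float:
        """Constant area offset of the eyespot pupil over the real pupil.

        Calibrated so the eyespot pupil is ``eyespot_pupil_area_ratio``
        times the real pupil area for a fish at the acquisition size
        (``gain_mean_mm``), using the mean axis ratio.  A constant
        offset keeps the pupil-pair regression at slope one with a
        positive intercept while staying inside the eyespot at all
        generated sizes.
        """
        r_mean = 0.5 * (AXIS_RATIO_RANGE[0] + AXIS_RATIO_RANGE[1])
        d_pupil = (
            self.pupil_fraction
            * self.allometry_coef
            * self.gain_mean_mm**self.allometry_exp
        )
        pupil_area_ref = math.pi / 4.0 * d_pupil**2 * r_mean
        return (self.eyespot_pupil_area_ratio - 1.0) * pupil_area_ref


def simulate_tree(
    n_species: int, rng: np.random.Generator, *, scale_to_unit_depth: bool = True
) -> Phylogeny:
    """Simulate a pure-birth (Yule, unit rate) tree.

    The tree starts from the root split (two lineages), each lineage
    splits at rate one, and simulation stops when ``n_species`` tips
    exist; tips extend through one further exponential waiting time so
    the final inter-event interval is complete.  By default all depths
    are rescaled so the root-to-tip depth is exactly one.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    width = len(str(n_species))
    root = dendropy.Node()
    birth: dict[dendropy.Node, float] = {root: 0.0}
    active = [root.new_child(), root.new_child()]
    t = 0.0
    birth[active[0]] = birth[active[1]] = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        for _ in range(2):
            child = node.new_child()
            birth[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_species)

    tree = dendropy.Tree()
    tree.seed_node = root
    namespace = tree.taxon_namespace
    scale = 1.0 / t_end if scale_to_unit_depth else 1.0
    for i, leaf in enumerate(sorted(active, key=lambda nd: birth[nd]), start=1):
        leaf.taxon = namespace.new_taxon(label=f"sp{i:0{width}d}")
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        # internal nodes die when they split; leaves live to t_end
        end_time = t_end if node.is_leaf() else min(birth[c] for c in node.child_nodes())
        node.edge.length = (end_time - birth[node]) * scale
    return Phylogeny(tree)


def _brownian_species_effects(
    tree: Phylogeny, sigma: float, rng: np.random.Generator
) -> dict[str, float]:
    """Brownian increments along the tree, returned per tip label."""
    values: dict[dendropy.Node, float] = {}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, sigma * math.sqrt(bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def simulate_dataset(
    tree: Phylogeny, cfg: GeneratorConfig
) -> tuple[Dataset, dict]:
    """Simulate a specimen dataset over the tips of ``tree``.

    Returns the dataset (which passes all data-model validation) and a
    truth dictionary holding every configuration value plus the realized
    per-species allometry coefficients, for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    species = sorted(tree.tip_labels)
    if len(species) < 2:
        raise ValueError("tree must have at least 2 tips")
    effects = _brownian_species_effects(tree, cfg.bm_sigma, rng)
    offset = cfg.eyespot_pupil_offset_mm2()
    lo, hi = cfg.specimens_per_species

    def draw_sl() -> float:
        # Specimen collections concentrate at intermediate sizes: sizes
        # are lognormal around the median, truncated to sl_range_mm.
        mu = math.log(cfg.sl_median_mm)
        while True:
            sl = math.exp(rng.normal(mu, cfg.sl_log_sd))
            if cfg.sl_range_mm[0] <= sl <= cfg.sl_range_mm[1]:
                return sl

    ds = Dataset()
    species_a = {}
    for sp in species:
        a = cfg.allometry_coef * math.exp(effects[sp])
        species_a[sp] = a
        n_spec = int(rng.integers(lo, hi + 1))
        for j in range(1, n_spec + 1):
            sl = draw_sl()
            gain = rng.normal(cfg.gain_mean_mm, cfg.gain_sd_mm)
            loss = rng.normal(cfg.loss_mean_mm, cfg.loss_sd_mm)
            present = bool(gain < sl < loss)
            rec = SpecimenRecord(
                species_id=sp,
                specimen_id=f"{sp}_{j:02d}",
                standard_length_mm=sl,
                eyespot_present=present,
                n_eyespots=1 if present else 0,
                source="synthetic",
            ).validate()
            ds.records.append(rec)
            if present:
                morph = _make_morphometrics(rec, a, offset, cfg, rng)
                if morph is not None:
                    ds.morphometrics.append(morph)
    truth = {
        "config": dataclasses.asdict(cfg),
        "eyespot_pupil_offset_mm2": offset,
        "species_allometry_coef": species_a,
    }
    return ds, truth


def _make_morphometrics(
    rec: SpecimenRecord,
    a: float,
    offset: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> MorphometricRecord | None:
    cv = cfg.measurement_cv
    sl = rec.standard_length_mm
    r_lo, r_hi = AXIS_RATIO_RANGE

    def jitter() -> float:
        return math.exp(rng.normal(0.0, cv)) if cv > 0 else 1.0

    def ratio() -> float:
        # cv = 0 pins the axis ratio too, so noise-free runs are exact circles
        return rng.uniform(r_lo, r_hi) if cv > 0 else 1.0

    # eye: maximum diameter from the allometric rule, elliptical area
    d_eye = min(a * sl**cfg.allometry_exp * jitter(), 0.5 * sl)
    area_eye = math.pi / 4.0 * d_eye**2 * ratio()
    # pupil nested inside the eye
    d_pupil = min(cfg.pupil_fraction * d_eye * jitter(), 0.8 * d_eye)
    area_pupil = math.pi / 4.0 * d_pupil**2 * ratio()
    # eyespot: area tracks eye area (isometry); diameter back-solved from
    # the area and its own axis ratio
    area_es = cfg.eyespot_area_ratio * area_eye * jitter()
    r_es = ratio()
    d_es = min(math.sqrt(4.0 * area_es / (math.pi * r_es)), 0.9 * sl)
    # eyespot pupil: real pupil area plus a constant offset (slope-one,
    # positive-intercept structure).  In the smallest fish the enlarged
    # pupil plus its pale ring does not fit inside an eye-sized eyespot;
    # such eyespots are not cleanly measurable and the specimen joins
    # the presence-only dataset (as most specimens do in collections).
    area_esp = (area_pupil + offset) * jitter()
    if area_esp > 0.9 * area_es:
        return None
    d_esp = min(math.sqrt(4.0 * area_esp / (math.pi * ratio())), 0.95 * d_es)
    return MorphometricRecord(
        specimen=rec,
        eye_diameter_mm=d_eye,
        pupil_diameter_mm=d_pupil,
        eyespot_diameter_mm=d_es,
        eyespot_pupil_diameter_mm=d_esp,
        eye_area_mm2=area_eye,
        pupil_area_mm2=area_pupil,
        eyespot_area_mm2=area_es,
        eyespot_pupil_area_mm2=area_esp,
    ).validate()


def write_simulation(
    outdir: str | Path, cfg: GeneratorConfig, *, header_comment: str | None = None
) -> dict[str, Path]:
    """Simulate and write the CSV, Newick and truth-JSON triple."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_species, rng)
    ds, truth = simulate_dataset(tree, cfg)
    paths = {
        "specimens": outdir / "specimens.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    write_specimens(ds, paths["specimens"], header_comment=header_comment)
    tree.write(paths["tree"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
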