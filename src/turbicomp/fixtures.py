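"""Synthetic test inputs: parametric meshes, calibration images, simulated clades.

Real turbinal CT surfaces are museum data; everything here is generated,
deterministic in (parameters, seed), and shaped to exercise the same code
paths.  Three families:

* meshes - icospheres (the CHNSI = 1 reference body) and scrolled
  thin-sheet solids mimicking the rolled maxilloturbinal, whose CHAR
  grows with the number of turns;
* binary images with known box-counting dimension (line 1, filled square
  2, Sierpinski gasket log3/log2, Koch curve log4/log3);
* simulated clades - a pure-birth ultrametric tree with diet regimes and
  trait values drawn from Brownian or multi-optimum OU models, emitted as
  a specimen table in the trait-module CSV schema.

The default clade mirrors the murine study design this toolkit targets:
55 species split 23 omnivorous / 18 carnivorous / 14 vermivorous, the
vermivores half terrestrial and half semi-fossorial, with vermivores given
a higher olfactory (and hence lower respiratory) relative-area optimum and
a narrower snout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line as _draw_line

from .evomodels import (
    RegimePainting,
    _lineage_segments,
    _ou_design,
    paint_regimes,
    simulate_bm,
    simulate_ou,
)
from .mesh import TriangleMesh
from .phylo import Phylogeny, pure_birth_tree

__all__ = [
    "ScrollMeshSpec",
    "CladeSimSpec",
    "make_icosphere",
    "make_scroll_mesh",
    "make_fractal_image",
    "simulate_clade",
]


# ------------------------------------------------------------------ meshes
def make_icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere with 20 * 4^s faces; vertices lie exactly on the sphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= subdivisions <= 7:
        raise ValueError("subdivisions must be in [0, 7]")
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh.from_trimesh(m, f"icosphere_s{subdivisions}_r{radius:g}")


@dataclass
class ScrollMeshSpec:
    """A rolled thin sheet: spiral cross-section extruded to a closed solid."""

    turns: float = 2.0
    height: float = 2.0  # extrusion length (z)
    thickness: float = 0.08  # sheet thickness
    gap: float = 0.45  # radial gap between successive whorls
    inner_radius: float = 0.5
    segments_per_turn: int = 96

    def __post_init__(self):
        if self.turns < 0.5:
            raise ValueError("need at least half a turn")
        if self.thickness >= self.gap:
            raise ValueError("thickness >= radial gap would self-intersect")
        if min(self.height, self.thickness, self.gap, self.inner_radius) <= 0:
            raise ValueError("all scroll dimensions must be positive")


def make_scroll_mesh(spec: ScrollMeshSpec) -> TriangleMesh:
    """Closed scroll solid: an Archimedean-spiral sheet of given thickness.

    The cross-section rectangle (thickness x height) is swept along the
    spiral ``r(t) = inner_radius + gap * t / 2pi``; side strips plus two
    end caps make a closed, orientable 2-manifold for all valid specs.
    """
    k = max(8, int(spec.segments_per_turn * spec.turns))
    t = np.linspace(0.0, 2.0 * math.pi * spec.turns, k + 1)
    r = spec.inner_radius + spec.gap * t / (2.0 * math.pi)
    half = spec.thickness / 2.0
    cos, sin = np.cos(t), np.sin(t)
    # cross-section corner loop (consistent winding): inner-bottom,
    # outer-bottom, outer-top, inner-top
    corners = []
    for dr, z in ((-half, 0.0), (half, 0.0), (half, spec.height), (-half, spec.height)):
        corners.append(np.column_stack([(r + dr) * cos, (r + dr) * sin,
                                        np.full_like(t, z)]))
    verts = np.concatenate(corners)  # 4 rings of k+1 samples
    n = k + 1
    faces = []
    for c in range(4):
        a0, b0 = c * n, ((c + 1) % 4) * n
        for i in range(k):
            # quad between ring c and ring c+1 along the sweep
            faces.append([a0 + i, b0 + i, b0 + i + 1])
            faces.append([a0 + i, b0 + i + 1, a0 + i + 1])
    # end caps (two triangles each, wound to face outward)
    faces.append([0 * n, 2 * n, 1 * n])
    faces.append([0 * n, 3 * n, 2 * n])
    faces.append([0 * n + k, 1 * n + k, 2 * n + k])
    faces.append([0 * n + k, 2 * n + k, 3 * n + k])
    return TriangleMesh(verts, np.asarray(faces),
                        f"scroll_t{spec.turns:g}")


# ------------------------------------------------------------------ images
def make_fractal_image(kind: str, size: int = 512, depth: int = 6) -> np.ndarray:
    """Deterministic binary calibration image.

    ``line`` - one horizontal single-pixel line (exactly `size` pixels);
    ``filled_square`` - all-foreground frame; ``sierpinski`` - gasket via
    the binomial parity pattern on a 2^depth grid scaled to `size`;
    ``koch`` - the Koch curve at the given recursion depth, rasterised.
    """
    if size < 256 and depth >= 5:
        raise ValueError("size >= 256 required for depth >= 5")
    img = np.zeros((size, size), dtype=bool)
    if kind == "line":
        img[size // 2, :] = True
    elif kind == "filled_square":
        img[:, :] = True
    elif kind == "sierpinski":
        g = 2 ** depth
        ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        pattern = (ii & jj) == 0  # Pascal-parity Sierpinski gasket
        rep = size // g
        if rep < 1:
            raise ValueError(f"size {size} too small for depth {depth}")
        img[: g * rep, : g * rep] = np.kron(pattern, np.ones((rep, rep), bool))
    elif kind == "koch":
        pts = [np.array([0.05, 0.5]), np.array([0.95, 0.5])]
        for _ in range(depth):
            new = [pts[0]]
            for a, b in zip(pts[:-1], pts[1:]):
                d = b - a
                perp = np.array([-d[1], d[0]]) * (math.sqrt(3) / 6.0)
                new += [a + d / 3.0, a + d / 2.0 + perp, a + 2.0 * d / 3.0, b]
            pts = new
        arr = (np.array(pts) * (size - 1)).round().astype(int)
        for a, b in zip(arr[:-1], arr[1:]):
            rr, cc = _draw_line(a[1], a[0], b[1], b[0])
            img[rr.clip(0, size - 1), cc.clip(0, size - 1)] = True
    else:
        raise ValueError(f"unknown fractal image kind {kind!r}")
    return img


# ------------------------------------------------------------------- clades
@dataclass
class CladeSimSpec:
    """Design of a simulated clade emulating the 55-species, 3-diet study.

    Diet counts default to 23 omnivorous / 18 carnivorous / 14 vermivorous
    with vermivores split evenly between terrestrial and semi-fossorial.
    The relative olfactory area evolves under a multi-optimum OU process;
    ``vermivore_effect_sd`` is the *realized* vermivorous tip shift in
    units of the OU stationary standard deviation (the carnivorous shift
    is half of it): the underlying optimum offsets are inflated by the
    inverse regime occupancy so the group mean actually expresses the
    stated distance despite finite time spent in the regime.
    Total turbinal area follows skull length allometrically with the
    strongly positive log-log slope typical of these data (2.25 by
    default) plus Brownian residual noise.
    """

    n_species: int = 55
    diet_counts: tuple[int, int, int] = (23, 18, 14)  # omni, carni, vermi
    semifossorial_fraction: float = 0.5  # of vermivores
    alpha: float = 2.0  # OU pull per unit tree depth
    stationary_sd: float = 0.03  # of RelatOlfaSA around its optimum
    base_relat_olfa: float = 0.55  # omnivorous optimum
    vermivore_effect_sd: float = 3.0  # optimum offsets in stationary-SD units
    allometric_slope: float = 2.25  # log TotSA ~ log SKL
    skl_root: float = 35.0  # mm, root skull length
    skl_sigma2: float = 0.03  # BM rate of log SKL
    tot_resid_sigma2: float = 0.01  # BM rate of allometric residual
    snw_base: float = 0.20  # snout width / skull length optimum (omnivores)
    snw_stationary_sd: float = 0.012
    noise_sd: float = 0.04  # lognormal measurement noise per specimen
    max_specimens: int = 3
    seed: int = 0

    def __post_init__(self):
        if sum(self.diet_counts) != self.n_species:
            raise ValueError("diet counts must sum to n_species")
        if min(self.diet_counts) < 1:
            raise ValueError("each diet needs at least one species")
        if self.stationary_sd <= 0 or self.alpha <= 0:
            raise ValueError("alpha and stationary_sd must be positive")


def _assign_clade_states(
    tree: Phylogeny, rng: np.random.Generator, counts: dict[str, int],
    base: str, max_clade: int = 8,
) -> pd.Series:
    """Assign derived states to randomly chosen clades (several origins per
    state), remaining tips keep the `base` state."""
    labels = pd.Series(np.full(tree.n_tips, base, dtype=object),
                       index=tree.tip_labels, name="diet")
    unassigned = set(tree.tip_labels)
    internal = [v for v in range(len(tree.parent)) if tree.children[v]]
    for state, want in counts.items():
        remaining = want
        while remaining > 0:
            candidates = []
            for v in internal:
                tips = [tree.labels[t] for t in tree.clade_nodes(v)
                        if not tree.children[t]]
                if 1 < len(tips) <= min(remaining, max_clade) and all(
                    t in unassigned for t in tips
                ):
                    candidates.append(tips)
            if candidates:
                chosen = candidates[int(rng.integers(len(candidates)))]
            else:  # fall back to a single tip origin
                chosen = [sorted(unassigned)[int(rng.integers(len(unassigned)))]]
            for tip in chosen:
                labels[tip] = state
                unassigned.discard(tip)
            remaining -= len(chosen)
    return labels


def _regime_occupancy(
    tree: Phylogeny, painting: RegimePainting, alpha: float, states: pd.Series
) -> dict[str, float]:
    """Mean OU design weight of each regime over its own tips.

    An optimum offset theta is only expressed at a tip in proportion to the
    lineage's exponentially-discounted time in the regime; dividing a
    desired tip-level shift by this occupancy yields the optimum offset
    that realises it on average.
    """
    seg = _lineage_segments(tree, painting)
    W = _ou_design(tree, seg, alpha, painting.n_regimes, tree.depth)
    aligned = np.asarray(states.loc[tree.tip_labels], dtype=object)
    occ = {}
    for k, r in enumerate(painting.regimes):
        mask = aligned == r
        occ[r] = float(W[mask, k].mean()) if mask.any() else 1.0
    return occ


# olfactory element shares of OlfaSA (sums to 1); respiratory shares of RespiSA
_OLFA_SHARES = {"ls": 0.12, "ft1": 0.18, "it": 0.10, "etI": 0.28, "etII": 0.18,
                "etIII": 0.14}
_RESPI_SHARES = {"nt": 0.30, "mt": 0.70}


def simulate_clade(spec: CladeSimSpec) -> tuple[Phylogeny, pd.DataFrame, pd.DataFrame]:
    """Simulate (tree, specimen table, species-level truth table).

    The specimen table matches the traits-module CSV schema; the truth
    table carries the species-level simulated values (including complexity
    indices OlfaCHAR/RespiCHAR evolving under the same diet regimes) for
    oracle-style checks.
    """
    rng = np.random.default_rng(spec.seed)
    tree = pure_birth_tree(spec.n_species, seed=spec.seed, depth=1.0)
    species = tree.tip_labels

    # diet assignment: exact counts, with derived diets occupying whole
    # clades (a few independent origins each), as in real vermivorous and
    # carnivorous murine radiations
    diet = _assign_clade_states(
        tree, rng,
        {"carnivorous": spec.diet_counts[1], "vermivorous": spec.diet_counts[2]},
        base="omnivorous", max_clade=8,
    )
    verm = [s for s in species if diet[s] == "vermivorous"]
    n_sf = int(round(len(verm) * spec.semifossorial_fraction))
    sf = set(list(rng.permutation(verm))[:n_sf])
    lifestyle = pd.Series(
        ["semi-fossorial" if s in sf else "terrestrial" for s in species],
        index=species, name="lifestyle",
    )

    painting = paint_regimes(tree, diet, method="parsimony")
    sd = spec.stationary_sd
    sigma2_ou = 2.0 * spec.alpha * sd ** 2
    # offsets are stated as realized tip-level shifts: divide by the regime
    # occupancy so the group mean actually lands the requested distance away
    occ = _regime_occupancy(tree, painting, spec.alpha, diet)
    gain = {r: 1.0 / max(o, 0.2) for r, o in occ.items()}
    theta = {
        "omnivorous": spec.base_relat_olfa,
        "carnivorous": spec.base_relat_olfa
        + 0.5 * spec.vermivore_effect_sd * sd * gain["carnivorous"],
        "vermivorous": spec.base_relat_olfa
        + spec.vermivore_effect_sd * sd * gain["vermivorous"],
    }
    relat_olfa = np.clip(
        simulate_ou(tree, painting, spec.alpha, sigma2_ou, theta, rng)[0],
        0.05, 0.95,
    )

    log_skl = simulate_bm(tree, spec.skl_sigma2, math.log(spec.skl_root), rng)[0]
    resid = simulate_bm(tree, spec.tot_resid_sigma2, 0.0, rng)[0]
    log_tot = (math.log(300.0) - spec.allometric_slope * math.log(spec.skl_root)
               + spec.allometric_slope * log_skl + resid)
    tot_sa = np.exp(log_tot)

    # snout width ratio: OU3-style structure (semi-fossorial vermivores narrowest)
    regime4 = pd.Series(
        [d if d != "vermivorous" else f"vermivorous-{lifestyle[s].replace('semi-', 'semi')}"
         for s, d in diet.items()], index=species,
    )
    painting4 = paint_regimes(tree, regime4, method="parsimony")
    ssd = spec.snw_stationary_sd
    occ4 = _regime_occupancy(tree, painting4, spec.alpha, regime4)
    gain4 = {r: 1.0 / max(o, 0.2) for r, o in occ4.items()}
    theta_snw = {
        "omnivorous": spec.snw_base,
        "carnivorous": spec.snw_base
        - 0.5 * spec.vermivore_effect_sd * ssd * gain4["carnivorous"],
        "vermivorous-terrestrial": spec.snw_base
        - spec.vermivore_effect_sd * ssd * gain4["vermivorous-terrestrial"],
        "vermivorous-semifossorial": spec.snw_base
        - 1.3 * spec.vermivore_effect_sd * ssd * gain4["vermivorous-semifossorial"],
    }
    snw_ratio = np.clip(
        simulate_ou(tree, painting4, spec.alpha, 2 * spec.alpha * ssd ** 2,
                    theta_snw, rng)[0],
        0.08, 0.35,
    )

    # complexity indices under the same diet regimes (vermivores: more
    # complex olfactory turbinals); plain OU on the index scale
    theta_char_o = {
        "omnivorous": 2.2,
        "carnivorous": 2.2 + 0.5 * spec.vermivore_effect_sd * 0.12 * gain["carnivorous"],
        "vermivorous": 2.2 + spec.vermivore_effect_sd * 0.12 * gain["vermivorous"],
    }
    olfa_char = np.clip(
        simulate_ou(tree, painting, spec.alpha, 2 * spec.alpha * 0.12 ** 2,
                    theta_char_o, rng)[0], 1.05, None)
    respi_char = np.clip(
        simulate_bm(tree, 0.01, 1.8, rng)[0], 1.05, None)

    truth = pd.DataFrame({
        "diet": diet, "lifestyle": lifestyle,
        "RelatOlfaSA": relat_olfa, "TotSA": tot_sa, "SKL": np.exp(log_skl),
        "SNW": snw_ratio * np.exp(log_skl), "SNL": 0.42 * np.exp(log_skl),
        "OlfaCHAR": olfa_char, "RespiCHAR": respi_char,
    }, index=pd.Index(species, name="species"))

    rows = []
    for i, sp in enumerate(species):
        n_spec = int(rng.integers(1, spec.max_specimens + 1))
        olfa_sa = relat_olfa[i] * tot_sa[i]
        respi_sa = tot_sa[i] - olfa_sa
        for j in range(n_spec):
            noise = lambda: float(np.exp(rng.normal(0.0, spec.noise_sd)))
            row = {"species": sp, "specimen": f"{sp}_{j + 1}"}
            for el, share in _RESPI_SHARES.items():
                row[el] = respi_sa * share * noise()
            for el, share in _OLFA_SHARES.items():
                row[el] = olfa_sa * share * noise()
            row["ft2"] = np.nan
            row["it2"] = np.nan
            row["SKL"] = truth.loc[sp, "SKL"] * noise()
            row["SNL"] = truth.loc[sp, "SNL"] * noise()
            row["SNW"] = truth.loc[sp, "SNW"] * noise()
            row["diet"] = diet[sp]
            row["lifestyle"] = lifestyle[sp]
            rows.append(row)
    cols = ["species", "specimen", "nt", "mt", "ls", "ft1", "ft2", "it", "it2",
            "etI", "etII", "etIII", "SKL", "SNL", "SNW", "diet", "lifestyle"]
    specimens = pd.DataFrame(rows)[cols]
    return tree, specimens, truth
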