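"""Synthetic study generator: two-guild outlines, traits, and trees.

The premaxilla profile is emulated by a fixed analytic template family
indexed by a blend parameter s in [0, 1]: s = 0 gives a wide, distally
flattened profile with a medial concavity (the blunt, grazer-like end
member) and s = 1 a narrow, elongate profile with a convex distal end
and medial lateral compression (the pointed, browser-like end member).
A simulated study draws per-specimen s values around two group means,
adds coordinate noise and nuisance translation/rotation/scale, attaches
an allometrically coupled body mass, simulates a Yule phylogeny over all
species, and records every true parameter for recovery checks.

All randomness derives from a single seed via ``numpy`` SeedSequence
spawning, so individual streams (shape, noise, nuisance, mass, tree) are
stable when other settings change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .io import CoordinateDataset
from .outline import SemilandmarkSet, points_at_arc_positions, _cumulative_arc_length
from .trees import parse_newick


@dataclass
class OutlineGenConfig:
    """Study-design parameters for the outline generator.

    Defaults mirror the emulated study design: 34 + 34 specimens with a
    known feeding class, 57 unknowns, group shape-blend means 0.2
    (browsers) and 0.8 (grazers) with within-group s.d. 0.1, coordinate
    noise 1% of outline scale, and 100 semilandmarks per outline.
    """

    n_browser: int = 34
    n_grazer: int = 34
    n_unknown: int = 57
    s_browser_mean: float = 0.2
    s_grazer_mean: float = 0.8
    s_sd: float = 0.1
    noise_sd: float = 0.01
    p: int = 100
    allometry_slope: float = 1.0
    mass_noise_sd: float = 0.5
    log_mass_base: float = np.log(1e5)  # ~100 kg, mid-range ruminant
    birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_browser, self.n_grazer, self.n_unknown) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.s_browser_mean <= 1.0 and 0.0 <= self.s_grazer_mean <= 1.0):
            raise ValueError("group s means must lie in [0, 1]")
        if self.noise_sd < 0 or self.s_sd < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass
class SimulatedStudy:
    coordinates: CoordinateDataset
    traits: pd.DataFrame
    tree: dendropy.Tree
    true_parameters: dict


def _half_template(s: float, n_dense: int = 4000) -> np.ndarray:
    """Dense left half of the template, from the start landmark to the apex.

    Parameterised by angle theta in [pi, pi/2]; the apex (theta = pi/2)
    sits on the midline x = 0.
    """
    theta = np.linspace(np.pi, np.pi / 2.0, n_dense)
    length = (1.0 - s) * 0.9 + s * 4.0           # blunt: wider than long
    sharp = (1.0 - s) * 0.4 + s * 1.2            # front exponent
    waist = 0.35 * s                             # medial lateral compression
    dip = 0.22 * (1.0 - s)                       # distal medial concavity
    x = np.cos(theta) * (1.0 - waist * np.sin(theta) ** 2)
    y = length * np.sin(theta) ** sharp - dip * np.exp(
        -(((theta - np.pi / 2.0) / 0.35) ** 2)
    )
    return np.column_stack([x, y])


def template_outline(s: float, p: int = 100) -> SemilandmarkSet:
    """Deterministic end-member blend outline with p equal-arc semilandmarks.

    Bilateral symmetry is exact by construction: the left half is
    sampled by arc length and mirrored about the midline.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("shape blend s must lie in [0, 1]")
    if p < 3:
        raise ValueError("p must be >= 3")
    half = _half_template(float(s))
    cum = _cumulative_arc_length(half)
    l_half = cum[-1]
    total = 2.0 * l_half
    step = total / (p - 1)
    pts = np.empty((p, 2))
    n_left = (p + 1) // 2
    left_positions = np.arange(n_left) * step
    left_positions = np.minimum(left_positions, l_half)
    pts[:n_left] = points_at_arc_positions(half, left_positions)
    for k in range(n_left, p):
        mirror = pts[p - 1 - k]
        pts[k] = (-mirror[0], mirror[1])
    if p % 2 == 1:
        pts[(p - 1) // 2, 0] = 0.0
    return SemilandmarkSet(species_id=f"template_s{s:g}", points=pts)


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    for i in range(size):
        v = rng.normal(mean, sd)
        while not 0.0 <= v <= 1.0:
            v = rng.normal(mean, sd)
        out[i] = v
    return out


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    rng: np.random.Generator | int = 0,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exactly ``n_tips``, ultrametric."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if labels is None:
        labels = [f"sp{i + 1:03d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("label count must equal n_tips")
    # each active lineage: (birth_time, subtree-newick or tip-slot)
    t = 0.0
    active: list[tuple[float, list]] = [(0.0, []), (0.0, [])]
    root_children = [active[0][1], active[1][1]]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        birth, slot = active.pop(idx)
        left, right = [], []
        slot.append(("node", t - birth, [left, right]))
        active.append((t, left))
        active.append((t, right))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(n_tips)
    for j, (birth, slot) in enumerate(active):
        slot.append(("tip", t - birth, labels[order[j]]))

    def render(slot) -> str:
        kind, bl, payload = slot[0]
        if kind == "tip":
            return f"{payload}:{float(bl)!r}"
        left, right = payload
        return f"({render(left)},{render(right)}):{float(bl)!r}"

    newick = f"({render(root_children[0])},{render(root_children[1])});"
    return parse_newick(newick)


def brownian_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    rng: np.random.Generator | int = 0,
    name: str = "trait",
) -> pd.Series:
    """Brownian-motion trait evolved along the tree's branches."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    values = {}
    tips = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = float(root_value)
        else:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            tips[node.taxon.label] = values[node]
    return pd.Series(tips, name=name).sort_index()


def simulate_tree_bm(
    n_tips: int,
    birth_rate: float = 1.0,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[dendropy.Tree, pd.Series]:
    """Yule tree plus one Brownian trait, from a single seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = simulate_yule(n_tips, birth_rate, rng)
    trait = brownian_traits(tree, sigma2=sigma2, root_value=root_value, rng=rng)
    return tree, trait


def generate_study(config: OutlineGenConfig) -> SimulatedStudy:
    """Simulate a full three-file study from one config.

    Per specimen: draw the shape blend s from its group's truncated
    normal; build the template at the configured p; add iid Gaussian
    coordinate noise scaled by the outline's bounding-box diagonal;
    apply random rotation U(0, 2pi), log-normal scale (sd 0.2), and
    Gaussian translation.  Unknowns draw s from a 50/50 mixture of the
    two group distributions.  Body mass is
    exp(base + allometry_slope * s + N(0, mass_noise_sd)) grams, and a
    Yule tree covers all species.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_shape, rng_noise, rng_nuisance, rng_mass, rng_tree = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    groups = (
        [("browser", config.s_browser_mean)] * config.n_browser
        + [("grazer", config.s_grazer_mean)] * config.n_grazer
    )
    for _ in range(config.n_unknown):
        mean = config.s_browser_mean if rng_shape.random() < 0.5 else config.s_grazer_mean
        groups.append(("unknown", mean))

    specimens, rows, true_s = [], [], {}
    counters = {"browser": 0, "grazer": 0, "unknown": 0}
    for cls, mean in groups:
        counters[cls] += 1
        sid = f"{cls}_{counters[cls]:02d}"
        s = float(_truncnorm01(rng_shape, mean, config.s_sd, 1)[0])
        true_s[sid] = s
        pts = template_outline(s, p=config.p).points.copy()
        scale = float(np.linalg.norm(np.ptp(pts, axis=0)))
        pts += rng_noise.normal(0.0, config.noise_sd * scale, size=pts.shape)
        angle = rng_nuisance.uniform(0.0, 2.0 * np.pi)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        factor = rng_nuisance.lognormal(0.0, 0.2)
        shift = rng_nuisance.normal(0.0, 2.0 * scale, size=2)
        pts = pts @ rot.T * factor + shift
        specimens.append(SemilandmarkSet(sid, pts))
        mass = np.exp(
            config.log_mass_base
            + config.allometry_slope * s
            + rng_mass.normal(0.0, config.mass_noise_sd)
        )
        rows.append({"species": sid, "feeding_class": cls, "body_mass_g": mass})

    traits = pd.DataFrame(rows).set_index("species")
    ids = [s.species_id for s in specimens]
    tree = simulate_yule(len(ids), config.birth_rate, rng_tree, labels=ids)
    return SimulatedStudy(
        coordinates=CoordinateDataset(specimens),
        traits=traits,
        tree=tree,
        true_parameters={"config": asdict(config), "true_s": true_s},
    )
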