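"""Seeded generators emulating the statistical structure of the assay data.

Four generators produce inputs with the structure each analysis stage
assumes, so the whole pipeline is testable without any external download:

* densitometry -- triplicate per-variant band densities with additive
  film offsets, multiplicative film scale, and Gaussian residual noise
  (one exposure of every variant per film);
* reporter -- ratio-scale reporter levels with lognormal multiplicative
  noise around configured true ratios plus an independent positive
  cotransfection covariate;
* alignment -- clade-structured promoter alignments evolved down a nested
  guide taxonomy by uniform (Jukes-Cantor-style) substitution, with a
  conserved block substituting at a reduced rate inside diverging flanks
  and an optional marsupial-style insertion;
* tree -- ultrametric (strict-clock) phylogenies with optional per-tip
  rate multipliers on the terminal branches.

Every generator is a pure function of its config (seed included): the same
config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .conservation import CLADE_ORDER, PromoterAlignment, TaxonomyTable
from .effectsize import AssayTable

__all__ = [
    "DensitometryConfig", "ReporterConfig", "AlignmentConfig", "TreeConfig",
    "gen_densitometry", "gen_reporter", "gen_alignment", "gen_tree",
]

_VARIANTS = ("PRE", "M1", "M2", "M3", "M4", "M5", "M6", "M7")
_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Densitometry
# ---------------------------------------------------------------------------


@dataclass
class DensitometryConfig:
    """Film-structured band-density simulation.

    ``delta`` are true standardized effects (in residual-SD units) of each
    variant relative to the control; each of ``n_films`` films carries one
    exposure of every variant, giving n = n_films replicates per variant.
    Film effects are additive offset ~ N(0, film_offset_sd) and
    multiplicative scale = 1 + N(0, film_scale_sd).
    """

    seed: int
    variants: tuple = _VARIANTS
    control: str = "PRE"
    n_films: int = 3
    delta: dict = field(default_factory=dict)
    film_offset_sd: float = 0.5
    film_scale_sd: float = 0.1
    residual_sd: float = 1.0
    assay_id: str = "sim-densitometry"


def gen_densitometry(cfg: DensitometryConfig) -> AssayTable:
    rng = np.random.default_rng(cfg.seed)
    mu = {v: cfg.delta.get(v, 0.0) * cfg.residual_sd for v in cfg.variants}
    records = []
    for f in range(1, cfg.n_films + 1):
        offset = rng.normal(0.0, cfg.film_offset_sd)
        scale = 1.0 + rng.normal(0.0, cfg.film_scale_sd)
        for v in cfg.variants:
            eps = rng.normal(0.0, cfg.residual_sd)
            records.append((f"film{f}", v, f, offset + scale * (mu[v] + eps)))
    df = pd.DataFrame(records,
                      columns=["film_id", "variant", "replicate", "signal"])
    return AssayTable(cfg.assay_id, "subtractive", df, cfg.control)


# ---------------------------------------------------------------------------
# Reporter
# ---------------------------------------------------------------------------


@dataclass
class ReporterConfig:
    """Ratio-scale reporter simulation with multiplicative noise.

    ``ratios`` are true expression ratios relative to the control (1.0);
    each replicate's signal is ratio * covariate * exp(N(0, sigma)) with an
    independent covariate ~ Uniform(covariate_range).
    """

    seed: int
    variants: tuple = _VARIANTS
    control: str = "PRE"
    n_reps: int = 3
    ratios: dict = field(default_factory=dict)
    sigma: float = 0.3
    covariate_range: tuple = (0.5, 2.0)
    assay_id: str = "sim-reporter"


def gen_reporter(cfg: ReporterConfig) -> AssayTable:
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.covariate_range
    records = []
    for rep in range(1, cfg.n_reps + 1):
        for v in cfg.variants:
            ratio = cfg.ratios.get(v, 1.0)
            cov = rng.uniform(lo, hi)
            sig = ratio * cov * np.exp(rng.normal(0.0, cfg.sigma))
            records.append((f"batch{rep}", v, rep, sig, cov))
    df = pd.DataFrame(records, columns=["film_id", "variant", "replicate",
                                        "signal", "covariate"])
    return AssayTable(cfg.assay_id, "ratio", df, cfg.control)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

# Default guide taxonomy: species per successively nested clade (innermost
# first) and a representative base weight for each level, patterned on a
# 35-taxon mammal sampling dominated by primates and rodents.
_DEFAULT_CLADE_SIZES = {"primates": 9, "euarchontoglires": 9,
                        "boreoeutheria": 9, "eutheria": 5, "mammals": 3}
_DEFAULT_BASE_WEIGHTS = {"primates": 11, "euarchontoglires": 9,
                         "boreoeutheria": 8, "eutheria": 4, "mammals": 1}


@dataclass
class AlignmentConfig:
    """Clade-structured alignment with a conserved block.

    Sequences evolve from a random ancestral sequence down the nested guide
    taxonomy; on every branch each site substitutes with probability
    ``branch_sub_prob`` (uniformly to another base), except inside the
    conserved block where the probability is multiplied by
    ``block_multiplier`` (< 1 conserved, 0 frozen, 1 neutral).  The block is
    given in reference promoter coordinates.  ``insertion_len`` > 0 adds a
    marsupial-only insertion (gap columns elsewhere) at the block midpoint.
    """

    seed: int
    length: int = 528
    ref_start: int = -326
    block: tuple = (-76, -47)
    block_multiplier: float = 0.25
    branch_sub_prob: float = 0.05
    clade_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_CLADE_SIZES))
    base_weights: dict = field(default_factory=lambda: dict(_DEFAULT_BASE_WEIGHTS))
    insertion_len: int = 0


def _ref_coords(ref_start: int, length: int) -> np.ndarray:
    coords = []
    pos = ref_start
    for _ in range(length):
        coords.append(pos)
        pos += 1
        if pos == 0:
            pos = 1
    return np.array(coords)


def _evolve(seq: np.ndarray, prob: np.ndarray, rng: np.random.Generator
            ) -> np.ndarray:
    hit = rng.random(seq.size) < prob
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (seq[hit] + shift) % 4
    return out


def gen_alignment(cfg: AlignmentConfig
                  ) -> tuple[PromoterAlignment, TaxonomyTable]:
    rng = np.random.default_rng(cfg.seed)
    coords = _ref_coords(cfg.ref_start, cfg.length)
    in_block = (coords >= cfg.block[0]) & (coords <= cfg.block[1])
    prob = np.where(in_block, cfg.branch_sub_prob * cfg.block_multiplier,
                    cfg.branch_sub_prob)
    ancestor = rng.integers(0, 4, size=cfg.length)
    # Chain of clade ancestors from the root inwards: mammals(root) ->
    # eutheria -> boreoeutheria -> euarchontoglires -> primates.
    chain = list(reversed(CLADE_ORDER))  # mammals ... primates
    clade_anc = {}
    current = ancestor
    for clade in chain:
        if clade != "mammals":  # root clade keeps the ancestral sequence
            current = _evolve(current, prob, rng)
        clade_anc[clade] = current
    ids, seqs, tax_rows = [], [], []
    for clade in CLADE_ORDER:  # innermost first: primates ... mammals
        size = cfg.clade_sizes.get(clade, 0)
        bw = cfg.base_weights.get(clade, 1)
        for i in range(1, size + 1):
            sp = f"{clade[:4]}_{i:02d}"
            tip = _evolve(clade_anc[clade], prob, rng)
            ids.append(sp)
            seqs.append(tip)
            tax_rows.append((sp, clade, bw, "synthetic"))
    reference = ids[0]  # first primate plays the human reference
    rows = [ "".join(_BASES[s]) for s in seqs ]
    if cfg.insertion_len > 0:
        mid = int(np.flatnonzero(in_block)[in_block.sum() // 2])
        new_rows = []
        for sp, row in zip(ids, rows):
            clade = sp.split("_")[0]
            if clade == "mamm":  # marsupial-style tips
                ins = "".join(_BASES[rng.integers(0, 4, cfg.insertion_len)])
            else:
                ins = "-" * cfg.insertion_len
            new_rows.append(row[:mid] + ins + row[mid:])
        rows = new_rows
    tax = TaxonomyTable(pd.DataFrame(
        tax_rows, columns=["species", "clade", "base_weight", "accession"]))
    aln = PromoterAlignment(ids, rows, reference, cfg.ref_start)
    return aln, tax


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclass
class TreeConfig:
    """Random clock tree with optional per-tip rate perturbation.

    A random topology is grown by successive coalescences with exponential
    waiting times and rescaled so the root sits at ``depth``; the result is
    ultrametric (all root-to-tip distances equal).  Coalescences are
    confined to the older (1 - min_tip_fraction) part of the depth, so
    every terminal branch is at least ``min_tip_fraction * depth`` and
    terminal-rate perturbations remain identifiable.  ``rate_multipliers``
    scale individual terminal branches (e.g. {"t05": 5.0} for a 5x-rate
    tip); ``rate_noise_sd`` adds Gaussian jitter to terminal branches.
    """

    seed: int
    n_tips: int = 35
    depth: float = 1.0
    clock: bool = True
    min_tip_fraction: float = 0.25
    rate_multipliers: dict = field(default_factory=dict)
    rate_noise_sd: float = 0.0
    labels: tuple = ()


def gen_tree(cfg: TreeConfig) -> dendropy.Tree:
    if cfg.n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(cfg.seed)
    labels = list(cfg.labels) if cfg.labels else [
        f"t{i:02d}" for i in range(1, cfg.n_tips + 1)]
    if len(labels) != cfg.n_tips:
        raise ValueError("labels length must equal n_tips")
    # (newick fragment without terminal colon, age, tip?) clusters
    clusters: list = [(lab, 0.0, lab) for lab in labels]
    age = 0.0
    while len(clusters) > 1:
        age += rng.exponential(1.0 / len(clusters))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        clusters[i] = (clusters[i], clusters[j], age)
        del clusters[j]
    root = clusters[0]
    f = cfg.min_tip_fraction

    def s(a: float) -> float:
        # map raw ages (0, age] onto [f*depth, depth]
        return cfg.depth * (f + (1.0 - f) * a / age)

    def build(node) -> str:
        (a, b, node_age) = node

        def child(c):
            if isinstance(c[0], str):  # tip: (label, 0.0, label)
                lab = c[0]
                length = s(node_age)
                length *= cfg.rate_multipliers.get(lab, 1.0)
                if cfg.rate_noise_sd > 0:
                    length = max(0.0, length + rng.normal(0.0, cfg.rate_noise_sd))
                return f"{lab}:{length:.10f}"
            return f"{build(c)}:{s(node_age) - s(c[2]):.10f}"

        return f"({child(a)},{child(b)})"

    newick = build(root) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
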