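"""Taxonomically weighted conservation analysis of an aligned promoter region.

A gapped multi-species alignment of the APP proximal promoter is scored
column by column with Shannon information content,

    R_i = 2 + sum_b p_b log2 p_b   (bits, in [0, 2]),

where the base frequencies p_b are weighted by per-species "working
weights" that partially compensate for over-representation of densely
sampled clades: each species carries a base weight (larger for species in
crowded clades), the raw weight is 2^(1/base_weight), and raw weights are
normalized within the analysis scope so the largest equals 1.  A fully
homogeneous column scores 2 bits; a uniform column scores 0.  No
small-sample correction is applied.

Derived summaries: a sliding-window track of mean R_i (default 100 nt,
roughly the internucleosome distance), weighted percent homology of a
region to the human reference (gaps count as mismatches), and sequence-logo
matrices (letter height = p_b * R_i, with bootstrap SDs over species).

Coordinates follow the promoter convention: positions ..., -2, -1, +1, +2
relative to the transcription start site, with no position 0.  The PRE is
the closed interval -76..-47 (30 positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

__all__ = [
    "CLADE_ORDER",
    "TaxonomyTable",
    "PromoterAlignment",
    "ColumnProfile",
    "working_weights",
    "column_info",
    "column_information_track",
    "window_track",
    "weighted_homology",
    "logo_matrix",
]

# Nested scopes, innermost first: primates c euarchontoglires c
# boreoeutheria c eutheria c mammals.
CLADE_ORDER = ["primates", "euarchontoglires", "boreoeutheria", "eutheria",
               "mammals"]

_BASES = np.array(["A", "C", "G", "T"])


class CoordinateError(ValueError):
    """A promoter coordinate is 0 or outside the aligned span."""


@dataclass
class TaxonomyTable:
    """Per-species clade membership, base weight, and accession.

    ``data`` columns: species, clade (the innermost clade the species
    belongs to, one of CLADE_ORDER), base_weight (positive integer),
    accession (free text).  Because the clades are nested, a species whose
    innermost clade is "primates" belongs to every scope, while a
    marsupial ("mammals") belongs only to the outermost.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species", "clade", "base_weight"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        bad = set(self.data["clade"]) - set(CLADE_ORDER)
        if bad:
            raise ValueError(f"unknown clades: {sorted(bad)}")
        if (self.data["base_weight"] < 1).any():
            raise ValueError("base weights must be >= 1")

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def members(self, scope: str) -> list[str]:
        """Species belonging to ``scope`` (nested membership)."""
        if scope not in CLADE_ORDER:
            raise ValueError(f"unknown scope {scope!r}")
        cutoff = CLADE_ORDER.index(scope)
        ranks = self.data["clade"].map(CLADE_ORDER.index)
        return list(self.data.loc[ranks <= cutoff, "species"])

    def base_weights(self) -> pd.Series:
        return self.data.set_index("species")["base_weight"]


def working_weights(tax: TaxonomyTable, scope: str) -> pd.Series:
    """Working weights 2^(1/base_weight), max-normalized within the scope.

    Species with small base weights (sparsely sampled clades) get the
    largest raw weights; the scope maximum is rescaled to exactly 1.
    """
    members = tax.members(scope)
    if not members:
        raise ValueError(f"scope {scope!r} is empty")
    bw = tax.base_weights().loc[members].astype(float)
    raw = np.power(2.0, 1.0 / bw)
    return raw / raw.max()


class PromoterAlignment:
    """Gapped species rows over {A, C, G, T, -} with a reference coordinate map.

    ``ref_start`` is the promoter coordinate of the first reference residue;
    coordinates increment along the ungapped reference, skipping 0.
    """

    def __init__(self, ids: list[str], seqs: list[str], reference: str,
                 ref_start: int):
        if ref_start == 0:
            raise CoordinateError("promoter coordinates have no position 0")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        if reference not in ids:
            raise ValueError(f"reference {reference!r} not in alignment")
        self.ids = list(ids)
        self.matrix = np.array([list(s.upper()) for s in seqs])
        self.reference = reference
        self.ref_start = ref_start
        ref_row = self.matrix[self.ids.index(reference)]
        self._ref_cols = np.flatnonzero(ref_row != "-")
        coords = []
        pos = ref_start
        for _ in self._ref_cols:
            coords.append(pos)
            pos += 1
            if pos == 0:
                pos = 1
        self._coords = np.array(coords)
        self._coord_to_col = dict(zip(coords, self._ref_cols))
        self._col_to_coord = dict(zip(self._ref_cols, coords))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_fasta(cls, path, reference: str, ref_start: int
                   ) -> "PromoterAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs],
                   reference, ref_start)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp, row in zip(self.ids, self.matrix):
                fh.write(f">{sp}\n{''.join(row)}\n")

    # -- coordinate map ------------------------------------------------------

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def ref_end(self) -> int:
        return int(self._coords[-1])

    def ref_to_col(self, position: int) -> int:
        """Alignment column holding the reference residue at ``position``."""
        if position == 0:
            raise CoordinateError("promoter coordinates have no position 0")
        try:
            return int(self._coord_to_col[position])
        except KeyError:
            raise CoordinateError(
                f"position {position} outside aligned span "
                f"{self.ref_start}..{self.ref_end}") from None

    def col_to_ref(self, column: int) -> int:
        """Reference coordinate of an alignment column (reference residue)."""
        try:
            return int(self._col_to_coord[column])
        except KeyError:
            raise CoordinateError(
                f"column {column} has no reference residue") from None

    def region_cols(self, start: int, end: int) -> np.ndarray:
        """Columns carrying reference residues of the closed region start..end."""
        c0, c1 = self.ref_to_col(start), self.ref_to_col(end)
        return self._ref_cols[(self._ref_cols >= c0) & (self._ref_cols <= c1)]

    def rows(self, species: list[str]) -> np.ndarray:
        idx = [self.ids.index(s) for s in species]
        return self.matrix[idx]


@dataclass
class ColumnProfile:
    """Weighted base frequencies and information content of one column."""

    freqs: dict
    info: float  # R_i, bits
    sd: float
    weight_sum: float
    n_residues: int


def _weighted_info(residues: np.ndarray, weights: np.ndarray
                   ) -> tuple[np.ndarray, float]:
    """(p_b over ACGT, R_i) for one column; gap rows carry no mass."""
    nongap = residues != "-"
    w = weights * nongap
    total = w.sum()
    p = np.array([(w * (residues == b)).sum() for b in _BASES]) / total
    nz = p[p > 0]
    ri = 2.0 + float((nz * np.log2(nz)).sum())
    return p, ri


def column_info(residues, weights, bootstrap: int = 0,
                rng: np.random.Generator | None = None) -> ColumnProfile:
    """Weighted base frequencies and information R_i of a single column.

    Frequencies are computed over non-gap rows only (weights renormalized
    to the non-gap mass); R_i = 2 + sum_b p_b log2 p_b, with no
    small-sample correction, so a homogeneous column scores exactly 2 bits.
    If ``bootstrap`` > 0, the SD of R_i is estimated by resampling species
    rows with replacement (seeded ``rng`` required).
    """
    residues = np.array([str(r).upper() for r in residues])
    weights = np.asarray(weights, float)
    if residues.shape != weights.shape:
        raise ValueError("residues and weights must have equal length")
    nongap = residues != "-"
    if nongap.sum() < 2:
        raise ValueError("column undefined: fewer than 2 non-gap residues")
    bad = set(residues[nongap]) - set(_BASES)
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    p, ri = _weighted_info(residues, weights)
    sd = 0.0
    if bootstrap > 0:
        if rng is None:
            raise ValueError("bootstrap SD requires a seeded rng")
        n = len(residues)
        vals = np.empty(bootstrap)
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            res_b, w_b = residues[idx], weights[idx]
            if (res_b != "-").sum() < 2 or w_b[res_b != "-"].sum() == 0:
                vals[b] = np.nan
                continue
            _, vals[b] = _weighted_info(res_b, w_b)
        sd = float(np.nanstd(vals, ddof=1))
    return ColumnProfile(freqs=dict(zip(_BASES, p)), info=ri, sd=sd,
                         weight_sum=float((weights * nongap).sum()),
                         n_residues=int(nongap.sum()))


def column_information_track(aln: PromoterAlignment, weights: pd.Series
                             ) -> np.ndarray:
    """Vectorized per-column R_i over the whole alignment.

    Columns with fewer than 2 non-gap residues among the weighted species
    are returned as NaN (undefined, excluded downstream).
    """
    rows = aln.rows(list(weights.index))
    w = weights.to_numpy(float)[:, None]
    nongap = rows != "-"
    total = (w * nongap).sum(axis=0)
    counts = nongap.sum(axis=0)
    ri = np.full(aln.n_columns, np.nan)
    ok = (counts >= 2) & (total > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = np.zeros(aln.n_columns)
        for b in _BASES:
            p = (w * (rows == b)).sum(axis=0) / np.where(total > 0, total, 1)
            term = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1)), 0.0)
            ent += term
    ri[ok] = 2.0 + ent[ok]
    return ri


def window_track(aln: PromoterAlignment, weights: pd.Series,
                 window: int = 100, alpha: float = 0.05,
                 mask_species: list[str] | None = None,
                 bonferroni_m: int = 1) -> pd.DataFrame:
    """Sliding-window mean information content with a t confidence interval.

    Columns gapped in any ``mask_species`` row (typically the primates) or
    with undefined R_i are excluded; the window slides over the remaining
    columns.  The CI is the Student t interval over the per-column values
    within each window, optionally Bonferroni-adjusted for ``bonferroni_m``
    clade-level comparisons.  Centers are reported in reference coordinates.
    """
    ri = column_information_track(aln, weights)
    usable = ~np.isnan(ri)
    if mask_species:
        gapped = (aln.rows(mask_species) == "-").any(axis=0)
        usable &= ~gapped
    cols = np.flatnonzero(usable)
    if window > cols.size:
        raise ValueError(
            f"window {window} exceeds {cols.size} usable columns")
    vals = ri[cols]
    a = alpha / bonferroni_m
    tcrit = stats.t.ppf(1 - a / 2, window - 1)
    out = []
    for i in range(cols.size - window + 1):
        win = vals[i:i + window]
        center_col = int(cols[i + window // 2])
        try:
            center = aln.col_to_ref(center_col)
        except CoordinateError:
            center = _nearest_ref_coord(aln, center_col)
        m = float(win.mean())
        hw = float(tcrit * win.std(ddof=1) / np.sqrt(window))
        out.append((center, m, m - hw, m + hw))
    return pd.DataFrame(out, columns=["center", "mean_bits", "ci_lo", "ci_hi"])


def _nearest_ref_coord(aln: PromoterAlignment, column: int) -> int:
    idx = int(np.argmin(np.abs(aln._ref_cols - column)))
    return int(aln._coords[idx])


def weighted_homology(aln: PromoterAlignment, region: tuple[int, int],
                      weights: pd.Series, reference: str | None = None
                      ) -> tuple[float, float]:
    """Weighted percent identity of a region to the reference, with SE.

    Per column, the weighted fraction of species (reference included,
    matching itself) whose residue equals the reference residue; gaps count
    as mismatches.  Returns (mean over columns * 100, SE over columns * 100).
    """
    reference = reference or aln.reference
    cols = aln.region_cols(*region)
    if cols.size == 0:
        raise CoordinateError("region contains no reference residues")
    species = list(weights.index)
    rows = aln.rows(species)[:, cols]
    ref_row = aln.matrix[aln.ids.index(reference)][cols]
    if np.any(ref_row == "-"):
        raise ValueError("reference has undefined residues in region")
    w = weights.to_numpy(float)[:, None]
    match = rows == ref_row[None, :]
    per_col = (w * match).sum(axis=0) / w.sum()
    mean = float(per_col.mean() * 100.0)
    se = float(per_col.std(ddof=1) / np.sqrt(per_col.size) * 100.0)
    return mean, se


def logo_matrix(aln: PromoterAlignment, region: tuple[int, int],
                weights: pd.Series, bootstrap: int = 1000,
                seed: int | None = None) -> pd.DataFrame:
    """Sequence-logo letter heights per region column.

    Letter height = p_b * R_i, so the four heights sum to the column's
    information content.  ``sd`` is the bootstrap SD of R_i over species
    (error-bar estimate); 0 when ``bootstrap`` = 0.
    """
    cols = aln.region_cols(*region)
    species = list(weights.index)
    rows = aln.rows(species)
    w = weights.to_numpy(float)
    rng = np.random.default_rng(seed) if bootstrap > 0 else None
    records = []
    for c in cols:
        prof = column_info(rows[:, c], w, bootstrap=bootstrap, rng=rng)
        rec = {"position": aln.col_to_ref(int(c))}
        rec.update({b: prof.freqs[b] * prof.info for b in _BASES})
        rec["info"] = prof.info
        rec["sd"] = prof.sd
        records.append(rec)
    return pd.DataFrame(records)


def region_summary(aln: PromoterAlignment, region: tuple[int, int],
                   tax: TaxonomyTable, scope: str, bootstrap: int = 1000,
                   seed: int | None = None) -> dict:
    """Clade-scope summary of a region: total R_i (bits) and % homology.

    Total R_i sums the per-column information over the reference-coordinate
    columns of the region (bounded by 2 bits per column); its SD combines
    the per-column bootstrap SDs in quadrature.
    """
    w = working_weights(tax, scope)
    logo = logo_matrix(aln, region, w, bootstrap=bootstrap, seed=seed)
    hom, hom_se = weighted_homology(aln, region, w)
    return {
        "scope": scope,
        "n_species": len(w),
        "region": list(region),
        "total_info_bits": float(logo["info"].sum()),
        "total_info_sd": float(np.sqrt((logo["sd"] ** 2).sum())),
        "homology_pct": hom,
        "homology_se": hom_se,
    }
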