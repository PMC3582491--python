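"""Literal TF-site scanning over PRE variants.

The catalog is a set of literal binding-site strings (forward strand, with
optional lowercase flanking-context letters matched case-insensitively)
and the factors' molecular weights.  Scanning is exact substring search;
variant-vs-wildtype site diffs are plain set algebra on (factor, site)
pairs; southwestern bands are matched to factors whose molecular weight
falls within a relative tolerance of the band estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import data as _data

__all__ = ["SiteCatalog", "SequenceVariant", "Match", "SiteDiff",
           "scan", "diff_sites", "match_band_to_tf", "default_catalog"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Match:
    factor: str
    site: str
    offset: int


@dataclass
class SiteCatalog:
    """factor -> literal site strings and molecular weights (kDa)."""

    factors: dict  # name -> {"sites": [...], "kda": [...]}

    def __post_init__(self) -> None:
        for name, entry in self.factors.items():
            if not entry["sites"] or any(not s for s in entry["sites"]):
                raise ValueError(f"empty site string for {name}")
            if any(k <= 0 for k in entry.get("kda", [])):
                raise ValueError(f"nonpositive molecular weight for {name}")

    @classmethod
    def from_tsv(cls, path) -> "SiteCatalog":
        df = pd.read_csv(path, sep="\t")
        factors: dict = {}
        for _, row in df.iterrows():
            entry = factors.setdefault(row["factor"], {"sites": [], "kda": []})
            entry["sites"].append(str(row["site"]))
            if "kda" in df.columns and pd.notna(row.get("kda")):
                kda = [float(x) for x in str(row["kda"]).split(",") if x]
                for k in kda:
                    if k not in entry["kda"]:
                        entry["kda"].append(k)
        return cls(factors)


def default_catalog() -> SiteCatalog:
    """The packaged PRE TF-site catalog."""
    return SiteCatalog({k: dict(v) for k, v in _data.TF_SITE_CATALOG.items()})


@dataclass
class SequenceVariant:
    """A PRE variant: 30-nt core with optional flanking context."""

    label: str
    core: str
    context_5p: str = ""
    context_3p: str = ""

    def __post_init__(self) -> None:
        seq = self.full_sequence
        bad = set(seq.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"invalid characters in {self.label}: {sorted(bad)}")

    @property
    def full_sequence(self) -> str:
        return self.context_5p + self.core + self.context_3p


@dataclass
class SiteDiff:
    deleted: set = field(default_factory=set)   # (factor, site) in wt only
    retained: set = field(default_factory=set)  # in both
    created: set = field(default_factory=set)   # in variant only

    def deleted_factors(self) -> set:
        return {f for f, _ in self.deleted}

    def created_factors(self) -> set:
        return {f for f, _ in self.created}


def scan(seq: SequenceVariant, catalog: SiteCatalog,
         reverse_complement: bool = False) -> list[Match]:
    """All case-insensitive exact catalog-site occurrences in the sequence.

    Forward strand by default (the catalog lists forward-strand strings);
    ``reverse_complement`` additionally scans the reverse complement,
    reporting offsets on the forward sequence.
    """
    text = seq.full_sequence.upper()
    targets = [text]
    if reverse_complement:
        targets.append(text.translate(_COMPLEMENT)[::-1])
    matches = []
    for factor, entry in catalog.factors.items():
        for site in entry["sites"]:
            pat = site.upper()
            for t_i, t in enumerate(targets):
                start = 0
                while True:
                    pos = t.find(pat, start)
                    if pos < 0:
                        break
                    off = pos if t_i == 0 else len(text) - pos - len(pat)
                    matches.append(Match(factor, site, off))
                    start = pos + 1
    return matches


def diff_sites(wildtype: SequenceVariant, variant: SequenceVariant,
               catalog: SiteCatalog) -> SiteDiff:
    """Set difference of scan results between wildtype and a variant."""
    wt = {(m.factor, m.site) for m in scan(wildtype, catalog)}
    var = {(m.factor, m.site) for m in scan(variant, catalog)}
    return SiteDiff(deleted=wt - var, retained=wt & var, created=var - wt)


def match_band_to_tf(band_kda: float, catalog: SiteCatalog,
                     tolerance: float = 0.10) -> list[str]:
    """Factors with a molecular weight within band +/- tolerance*band (closed)."""
    if band_kda <= 0:
        raise ValueError("band molecular weight must be positive")
    lo, hi = band_kda * (1 - tolerance), band_kda * (1 + tolerance)
    return sorted(
        name for name, entry in catalog.factors.items()
        if any(lo <= k <= hi for k in entry.get("kda", []))
    )
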