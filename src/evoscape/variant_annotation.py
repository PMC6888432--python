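"""Context annotation of pathogenic missense variants.

Each variant (reference coordinates) is joined to its residue's domain
membership, structure/rate category and distance to the nearest conserved
phosphosite, and the variant set is summarized as a contingency table over
(domain vs non-domain) x (ordered vs disordered) x (slow vs fast), both
site-weighted (each mutated position once) and case-weighted (summing
reported case counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import FormatError, VariantRecord
from .structure_disorder import ResidueClassification

__all__ = [
    "DomainAnnotation",
    "VariantContext",
    "read_domains",
    "annotate_variants",
    "summarize_distribution",
]


@dataclass
class DomainAnnotation:
    """Named 1-based inclusive intervals on the reference sequence."""

    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (start, end) in self.intervals.items():
            if not (1 <= start <= end):
                raise ValueError(f"domain {name!r}: bad interval {start}-{end}")

    def domain_of(self, pos: int) -> str | None:
        for name, (start, end) in self.intervals.items():
            if start <= pos <= end:
                return name
        return None


def read_domains(path: str | Path) -> DomainAnnotation:
    """Read a domain interval file: ``name<TAB>start<TAB>end``."""
    intervals: dict[str, tuple[int, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"bad domain line: {line!r}")
        name, start, end = parts[0], int(parts[1]), int(parts[2])
        if name in intervals:
            raise FormatError(f"duplicate domain name {name!r}")
        intervals[name] = (start, end)
    return DomainAnnotation(intervals)


@dataclass
class VariantContext:
    variant: VariantRecord
    in_domain: str | None
    structure_category: str   # ordered / constrained_disorder / flexible_disorder / no_data
    structure: str            # ordered / disordered / no_data
    evolution: str            # slow / fast / no_data
    z: float
    distance_to_nearest_conserved_ptm: int | None  # 0 = overlap; None if no PTMs
    flagged: bool = False     # position lacked a classification


def annotate_variants(variants: list[VariantRecord],
                      domains: DomainAnnotation,
                      classification: ResidueClassification,
                      ptm_positions: list[int]) -> list[VariantContext]:
    """Join each variant to domain, structure/rate class and nearest PTM."""
    cls = classification.table.set_index("pos")
    ptm = np.asarray(sorted(ptm_positions), dtype=int)
    out: list[VariantContext] = []
    for v in variants:
        dist = int(np.min(np.abs(ptm - v.position))) if len(ptm) else None
        if v.position in cls.index:
            row = cls.loc[v.position]
            out.append(VariantContext(
                variant=v, in_domain=domains.domain_of(v.position),
                structure_category=row["category"], structure=row["structure"],
                evolution=row["evolution"], z=float(row["z"]),
                distance_to_nearest_conserved_ptm=dist))
        else:
            out.append(VariantContext(
                variant=v, in_domain=domains.domain_of(v.position),
                structure_category="no_data", structure="no_data",
                evolution="no_data", z=float("nan"),
                distance_to_nearest_conserved_ptm=dist, flagged=True))
    return out


def summarize_distribution(contexts: list[VariantContext]) -> pd.DataFrame:
    """Contingency counts over (domain, structure, evolution) cells.

    Returns one row per cell with ``n_sites`` (each variant record once) and
    ``n_cases`` (case-weighted). Cells with no_data axes are kept under the
    'no_data' level so totals always equal the input.
    """
    if not contexts:
        raise ValueError("no variant contexts to summarize")
    rows = []
    for c in contexts:
        rows.append((
            "domain" if c.in_domain else "non_domain",
            c.structure,
            c.evolution,
            1,
            c.variant.n_cases,
        ))
    df = pd.DataFrame(rows, columns=["region", "structure", "evolution",
                                     "n_sites", "n_cases"])
    out = (df.groupby(["region", "structure", "evolution"], as_index=False)
             .sum(numeric_only=True))
    return out
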