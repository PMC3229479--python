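"""Risk-panel definitions and I/O.

A *panel* is an ordered list of biallelic risk loci, each described by the
risk-allele frequency in the control (reference) population and the
per-allele odds ratio.  The packaged panels transcribe the published
genome-wide-significant MS susceptibility loci:

``panel_24``
    The 24 well-replicated loci (23 non-MHC loci plus the HLA-DRB1*15:01
    tag SNP rs3135388, OR 3.08 at control RAF 0.13).
``panel_53``
    ``panel_24`` plus the 29 novel loci from the same collaboration.
``panel_6``
    The six replicated loci whose genes were typed in the empirical
    case-control study (HLA-DRB, EVI5, CD58, IL7R, IL2RA, CLEC16A),
    parameterised with the replicated frequencies and odds ratios.
``panel_empirical_6``
    The six SNPs as observed in the case-control cohort itself (control
    RAFs and crude ORs); used as the generative target for synthetic
    cohorts.

Loci are abstract: no genome coordinates, strand harmonisation or LD
information is carried.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "VariantSpec",
    "Panel",
    "StudyConfig",
    "PanelFormatError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "builtin_panel",
    "BUILTIN_PANEL_NAMES",
]

_COLUMNS = ("gene", "rsid", "chrom", "risk_allele", "raf", "or")

# genes of the empirical study, in the order they are reported
_EMPIRICAL_GENES = ("HLA-DRB", "EVI5", "CD58", "IL7R", "IL2RA", "CLEC16A")

BUILTIN_PANEL_NAMES = ("panel_6", "panel_24", "panel_53", "panel_empirical_6")


class PanelFormatError(ValueError):
    """A panel file is structurally malformed (missing/extra columns)."""


class PanelValidationError(ValueError):
    """A variant's parameters are outside their valid domain."""


@dataclass(frozen=True)
class VariantSpec:
    """One risk locus.

    Parameters
    ----------
    raf_controls
        Risk-allele frequency in the control/reference population.
        Must lie strictly inside (0, 1) for any variant used in
        simulation.
    per_allele_or
        Odds ratio per copy of the risk allele (multiplicative model:
        the homozygote odds ratio is its square).
    """

    gene_symbol: str
    rsid: str
    chromosome: str
    risk_allele: str
    raf_controls: float
    per_allele_or: float

    def validate(self) -> "VariantSpec":
        if not (0.0 < self.raf_controls < 1.0):
            raise PanelValidationError(
                f"{self.rsid}: risk-allele frequency {self.raf_controls} "
                "must lie strictly in (0, 1)"
            )
        if not self.per_allele_or > 0.0:
            raise PanelValidationError(
                f"{self.rsid}: per-allele OR {self.per_allele_or} must be > 0"
            )
        return self


@dataclass(frozen=True)
class Panel:
    """An ordered collection of risk loci with unique rsids.

    Column order of genotype matrices downstream always follows panel
    order.
    """

    name: str
    variants: tuple[VariantSpec, ...]

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelValidationError(
                f"panel {self.name!r}: duplicate rsids {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantSpec]:
        return iter(self.variants)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    def subset(self, rsids: Iterable[str], name: str | None = None) -> "Panel":
        """Panel restricted to ``rsids``, keeping current order."""
        keep = set(rsids)
        missing = keep - set(self.rsids)
        if missing:
            raise KeyError(f"rsids not in panel {self.name!r}: {sorted(missing)}")
        return Panel(
            name=name or f"{self.name}_subset",
            variants=tuple(v for v in self.variants if v.rsid in keep),
        )

    def drop(self, rsids: Iterable[str], name: str | None = None) -> "Panel":
        """Panel with ``rsids`` removed (used e.g. to exclude HLA)."""
        gone = set(rsids)
        return Panel(
            name=name or f"{self.name}_drop",
            variants=tuple(v for v in self.variants if v.rsid not in gone),
        )

    def extend(self, extra: Iterable[VariantSpec], name: str | None = None) -> "Panel":
        return Panel(
            name=name or self.name,
            variants=self.variants + tuple(extra),
        )


@dataclass(frozen=True)
class StudyConfig:
    """Scalar parameters of a simulation run.

    Defaults follow the study design: lifetime MS risk 0.1%, populations
    of 100,000 individuals, and 100 repetitions per scenario.
    """

    population_risk: float = 0.001
    n_individuals: int = 100_000
    n_reps: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.population_risk < 1.0):
            raise PanelValidationError(
                f"population_risk {self.population_risk} must lie in (0, 1)"
            )
        if self.n_individuals < 1:
            raise PanelValidationError("n_individuals must be >= 1")
        if self.n_reps < 1:
            raise PanelValidationError("n_reps must be >= 1")

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def _parse_row(fields: dict[str, str], lineno: int) -> VariantSpec:
    try:
        raf = float(fields["raf"])
        or_ = float(fields["or"])
    except ValueError as exc:
        raise PanelFormatError(f"line {lineno}: non-numeric raf/or: {exc}") from exc
    return VariantSpec(
        gene_symbol=fields["gene"],
        rsid=fields["rsid"],
        chromosome=fields["chrom"],
        risk_allele=fields["risk_allele"],
        raf_controls=raf,
        per_allele_or=or_,
    ).validate()


def read_panel(path: str | Path, name: str | None = None) -> Panel:
    """Read a tab-separated panel file.

    The file must carry a header line naming the six columns
    ``gene, rsid, chrom, risk_allele, raf, or`` (any order); one variant
    per subsequent row, returned in file order.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        missing = [c for c in _COLUMNS if c not in cols]
        if missing:
            raise PanelFormatError(
                f"{path}: header is missing column(s) {missing}; got {cols}"
            )
        variants = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            if len(values) != len(cols):
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(values)}"
                )
            variants.append(_parse_row(dict(zip(cols, values)), lineno))
    return Panel(name=name or path.stem, variants=tuple(variants))


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write ``panel`` as TSV; ``read_panel`` round-trips it losslessly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for v in panel.variants:
            fh.write(
                "\t".join(
                    [
                        v.gene_symbol,
                        v.rsid,
                        v.chromosome,
                        v.risk_allele,
                        repr(v.raf_controls),
                        repr(v.per_allele_or),
                    ]
                )
                + "\n"
            )


def _packaged(fname: str, name: str) -> Panel:
    ref = importlib.resources.files("msrisk.data").joinpath(fname)
    with importlib.resources.as_file(ref) as p:
        return read_panel(p, name=name)


def builtin_panel(name: str) -> Panel:
    """Return one of the packaged panels by name.

    ``panel_6`` is assembled from the replicated 24-variant table by
    selecting the rows for the six empirically typed genes (the
    simulation scenarios use the replicated effect sizes for these, not
    the cohort-observed ones, which live in ``panel_empirical_6``).
    """
    if name not in BUILTIN_PANEL_NAMES:
        raise KeyError(
            f"unknown builtin panel {name!r}; valid names: {BUILTIN_PANEL_NAMES}"
        )
    if name == "panel_24":
        return _packaged("panel_24.tsv", "panel_24")
    if name == "panel_53":
        p24 = _packaged("panel_24.tsv", "panel_24")
        p29 = _packaged("panel_29_novel.tsv", "panel_29_novel")
        return Panel(name="panel_53", variants=p24.variants + p29.variants)
    if name == "panel_empirical_6":
        return _packaged("panel_empirical_6.tsv", "panel_empirical_6")
    # panel_6: Table-2 rows for the six empirical genes, HLA first
    p24 = _packaged("panel_24.tsv", "panel_24")
    by_gene = {v.gene_symbol: v for v in p24.variants}
    return Panel(
        name="panel_6",
        variants=tuple(by_gene[g] for g in _EMPIRICAL_GENES),
    )
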