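"""Closed-form estimate of the STRA8-expressing preleptotene fraction of the
adult mouse testis, and the enrichment fold achieved by spermatogenesis
synchronization.

The arithmetic chains published stereology and staging constants: per-testis
cell-type counts, the durations of seminiferous-epithelium stages VI-VIII, the
fraction of each stage during which preleptotene spermatocytes are present,
and the fraction of tubules at each stage with STRA8-positive spermatocytes.
Two rounding modes exist: ``unrounded`` (default) carries full precision;
``paper`` rounds intermediates exactly as the published derivation does (the
preleptotene count is rounded to 3.0 million before the 62.5% multiplication)
so the printed numbers are matched digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

STAGES = ("VI", "VII", "VIII")


@dataclass(frozen=True)
class CellCensus:
    """Per-testis cell-type counts in units of 10^6 cells."""

    sertoli: float = 3.0
    spermatogonia: float = 2.8
    spermatocytes: float = 25.0
    spermatids: float = 99.0
    interstitial: float = 3.5

    def __post_init__(self) -> None:
        for name in ("sertoli", "spermatogonia", "spermatocytes", "spermatids", "interstitial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")


@dataclass(frozen=True)
class StageTable:
    """Stage durations (hours) and occupancy fractions for stages VI-VIII.

    ``presence`` is the fraction of each stage during which preleptotene cells
    are present (later half of VI, all of VII, first half of VIII).
    ``stra8_fraction`` is the fraction of tubules at each stage containing
    STRA8-positive spermatocytes. ``total_spermatocyte_hr`` is the full
    spermatocyte lifespan.
    """

    duration_hr: Mapping[str, float] = field(
        default_factory=lambda: {"VI": 18.1, "VII": 20.6, "VIII": 20.8}
    )
    presence: Mapping[str, float] = field(
        default_factory=lambda: {"VI": 0.5, "VII": 1.0, "VIII": 0.5}
    )
    stra8_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"VI": 0.0, "VII": 0.71, "VIII": 1.0}
    )
    total_spermatocyte_hr: float = 326.0

    def __post_init__(self) -> None:
        for s in STAGES:
            if self.duration_hr[s] <= 0:
                raise ValueError(f"duration of stage {s} must be > 0")
            for frac in (self.presence[s], self.stra8_fraction[s]):
                if not 0.0 <= frac <= 1.0:
                    raise ValueError("stage fractions must lie in [0, 1]")
        if self.total_spermatocyte_hr <= 0:
            raise ValueError("total spermatocyte lifespan must be > 0")


PAPER_CENSUS = CellCensus()
PAPER_STAGES = StageTable()


def total_cells(c: CellCensus) -> float:
    """Total cells per testis, in units of 10^6."""
    return c.sertoli + c.spermatogonia + c.spermatocytes + c.spermatids + c.interstitial


def preleptotene_lifespan(s: StageTable) -> float:
    """Hours spent as a preleptotene spermatocyte: sum of duration x presence."""
    return sum(s.duration_hr[v] * s.presence[v] for v in STAGES)


def stra8_expression_duration(s: StageTable) -> float:
    """Hours of STRA8 expression: sum of duration x presence x STRA8 tubule fraction."""
    return sum(s.duration_hr[v] * s.presence[v] * s.stra8_fraction[v] for v in STAGES)


@dataclass(frozen=True)
class CensusReport:
    """Full chain of the composition estimate. Counts in 10^6 cells."""

    mode: str
    total_cells_millions: float
    spermatocyte_fraction: float
    preleptotene_lifespan_hr: float
    preleptotene_fraction_of_spermatocytes: float
    preleptotene_fraction_of_all: float
    preleptotene_count_millions: float
    stra8_duration_hr: float
    stra8_fraction_of_preleptotene: float
    stra8_preleptotene_count_millions: float
    stra8_preleptotene_fraction_of_all: float
    observed_2s_fraction: float
    enrichment_fold: float

    def to_dict(self) -> dict[str, float | str]:
        return dict(self.__dict__)

    def __str__(self) -> str:
        f = self
        pct = lambda x: f"{100 * x:g}%"
        return "\n".join(
            [
                f"total cells per testis:            {f.total_cells_millions:g} x 10^6",
                f"spermatocytes, of all cells:       {pct(f.spermatocyte_fraction)}",
                f"preleptotene lifespan:             {f.preleptotene_lifespan_hr:g} hr",
                f"preleptotene, of spermatocytes:    {pct(f.preleptotene_fraction_of_spermatocytes)}",
                f"preleptotene, of all cells:        {pct(f.preleptotene_fraction_of_all)}",
                f"preleptotene cells per testis:     {f.preleptotene_count_millions:g} x 10^6",
                f"STRA8 expression duration:         {f.stra8_duration_hr:g} hr",
                f"STRA8+, of preleptotene:           {pct(f.stra8_fraction_of_preleptotene)}",
                f"STRA8+ preleptotene per testis:    {f.stra8_preleptotene_count_millions:g} x 10^6",
                f"STRA8+ preleptotene, of all cells: {pct(f.stra8_preleptotene_fraction_of_all)}",
                f"observed 2S fraction:              {pct(f.observed_2s_fraction)}",
                f"synchronization enrichment:        {f.enrichment_fold:g}-fold",
            ]
        )


def census_report(
    c: CellCensus = PAPER_CENSUS,
    s: StageTable = PAPER_STAGES,
    observed_2s_fraction: float = 0.44,
    rounding_mode: str = "unrounded",
) -> CensusReport:
    """Compute the full composition chain.

    In unrounded mode the chain collapses algebraically:
    stra8_fraction_of_all = spermatocyte_fraction x stra8_duration / lifespan_total.
    Paper mode reproduces the published rounding at each printed step.
    """
    if not 0.0 < observed_2s_fraction <= 1.0:
        raise ValueError("observed_2s_fraction must be in (0, 1]")
    if rounding_mode not in {"unrounded", "paper"}:
        raise ValueError(f"unknown rounding_mode {rounding_mode!r}")
    total = total_cells(c)
    if total <= 0 or c.spermatocytes <= 0:
        raise ValueError("census must contain spermatocytes and a positive total")
    lifespan = preleptotene_lifespan(s)
    duration = stra8_expression_duration(s)
    if lifespan <= 0:
        raise ValueError("preleptotene lifespan is zero; chain undefined")

    if rounding_mode == "paper":
        sperm_frac = round(c.spermatocytes / total, 3)                    # 18.8%
        lifespan = round(lifespan)                                        # ~40 hr
        prelep_of_sperm = round(lifespan / s.total_spermatocyte_hr, 3)    # 12.3%
        prelep_of_all = round(sperm_frac * prelep_of_sperm, 3)            # 2.3%
        prelep_count = round(prelep_of_all * total, 1)                    # ~3.1 x 10^6
        duration = round(duration)                                        # ~25 hr
        stra8_of_prelep = duration / lifespan                             # 62.5%
        # the published chain rounds the preleptotene count down to 3.0 x 10^6
        # before applying the 62.5% multiplier
        stra8_count = round(stra8_of_prelep * round(prelep_count, 0), 2)  # 1.88 x 10^6
        stra8_of_all = round(stra8_count / total, 3)                      # ~1.4%
        enrichment = round(observed_2s_fraction / (stra8_count / total))  # 31-fold
    else:
        sperm_frac = c.spermatocytes / total
        prelep_of_sperm = lifespan / s.total_spermatocyte_hr
        prelep_of_all = sperm_frac * prelep_of_sperm
        prelep_count = prelep_of_all * total
        stra8_of_prelep = duration / lifespan
        stra8_count = stra8_of_prelep * prelep_count
        stra8_of_all = stra8_count / total
        enrichment = observed_2s_fraction / stra8_of_all

    return CensusReport(
        mode=rounding_mode,
        total_cells_millions=total,
        spermatocyte_fraction=sperm_frac,
        preleptotene_lifespan_hr=lifespan,
        preleptotene_fraction_of_spermatocytes=prelep_of_sperm,
        preleptotene_fraction_of_all=prelep_of_all,
        preleptotene_count_millions=prelep_count,
        stra8_duration_hr=duration,
        stra8_fraction_of_preleptotene=stra8_of_prelep,
        stra8_preleptotene_count_millions=stra8_count,
        stra8_preleptotene_fraction_of_all=stra8_of_all,
        observed_2s_fraction=observed_2s_fraction,
        enrichment_fold=enrichment,
    )
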