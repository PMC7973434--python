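"""Run configuration: dataclasses, defaults and validation.

The on-disk format is a YAML mapping (see ``docs/formats.md``).  Unknown keys
are rejected, defaults are filled in, and a resolved configuration can be
round-tripped through :meth:`Config.to_dict` / :func:`config_from_dict`
without change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from .errors import ConfigError

#: Analysis thresholds used throughout the pipeline.
DEFAULT_ALPHA = 0.05            # significance cut on BH-adjusted p-values
DEFAULT_LINKAGE_WINDOW = 500_000  # bp; +/- window around the query locus
DEFAULT_ENRICHMENT_FDR = 0.1    # BH FDR threshold for term enrichment
DEFAULT_MIN_FRACTION = 0.1      # failed-mutant call: median < fraction * plate median


@dataclass
class QuerySpec:
    """One query strain crossed against the whole library.

    ``locus`` names the gene in the genome map where the query mutation sits
    (drives the linkage artifact and the linkage filter).  ``locus=None``
    lets the simulator place the locus deterministically along the genome.
    """

    name: str
    locus: str | None = None
    control: bool = False
    fraction_positive: float = 0.05
    fraction_negative: float = 0.05
    effect_mean: float = 1.0
    effect_sd: float = 0.25

    def validate(self) -> list[str]:
        problems = []
        if not self.name:
            problems.append("query name must be non-empty")
        if not 0 <= self.fraction_positive <= 1 or not 0 <= self.fraction_negative <= 1:
            problems.append(f"query {self.name}: fractions must lie in [0, 1]")
        elif self.fraction_positive + self.fraction_negative > 1:
            problems.append(
                f"query {self.name}: fraction_positive + fraction_negative > 1"
            )
        if self.effect_sd < 0:
            problems.append(f"query {self.name}: effect_sd must be >= 0")
        return problems


def _default_queries() -> list[QuerySpec]:
    # One control plus three mutant alleles, mirroring a three-allele screen
    # against a neutral control query.
    return [
        QuerySpec(name="ctrl", control=True, fraction_positive=0.0, fraction_negative=0.0),
        QuerySpec(name="mutA"),
        QuerySpec(name="mutB"),
        QuerySpec(name="mutC"),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic screen generator.

    Colony sizes are generated on a log2-normal scale around ``base``; the
    residual SD follows a decreasing trend in the expected log2 size
    (``sigma0``, ``trend_strength``) and a fraction ``rho`` of the residual
    variance is shared by the four colonies of a quadruplicate.
    """

    n_genes: int = 1000
    n_chromosomes: int = 3
    spacing: int = 20_000            # bp between gene starts on a chromosome
    queries: list[QuerySpec] = field(default_factory=_default_queries)
    n_batches: int = 3
    quad: int = 4                    # colonies per double mutant per plate (2x2 block)
    plate_rows: int = 32
    plate_cols: int = 48
    sigma0: float = 0.3              # baseline log2 residual SD
    trend_strength: float = 0.5      # SD inflation per log2 unit below the reference size
    rho: float = 0.25                # intra-quadruplicate variance fraction
    batch_sd: float = 0.3            # SD of per-batch log2 offsets
    rowcol_sd: float = 0.1           # SD of per-row / per-column log2 offsets
    spatial_amplitude: float = 0.3   # amplitude of the smooth spatial field (log2)
    dropout_p: float = 0.02          # probability a colony fails to grow
    control_empty_quadrants: int = 8
    base: float = 10.0               # expected log2 size of a neutral colony
    linkage_penalty: float = 1.5     # peak log2 size penalty at the query locus
    linkage_window: int = DEFAULT_LINKAGE_WINDOW
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.n_genes < 1 or self.n_chromosomes < 1:
            problems.append("n_genes and n_chromosomes must be >= 1")
        if self.n_genes < self.n_chromosomes:
            problems.append("n_genes must be >= n_chromosomes")
        if self.spacing <= 0:
            problems.append("spacing must be > 0")
        if self.quad != 4:
            problems.append("quad must be 4 (2x2 pinning blocks)")
        if self.plate_rows % 2 or self.plate_cols % 2:
            problems.append("plate_rows and plate_cols must be even (2x2 blocks)")
        for name in ("sigma0", "trend_strength", "batch_sd", "rowcol_sd",
                     "spatial_amplitude", "linkage_penalty"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0 <= self.rho < 1:
            problems.append("rho must lie in [0, 1)")
        if not 0 <= self.dropout_p < 1:
            problems.append("dropout_p must lie in [0, 1)")
        if self.n_batches < 1:
            problems.append("n_batches must be >= 1")
        if self.control_empty_quadrants < 0:
            problems.append("control_empty_quadrants must be >= 0")
        if sum(q.control for q in self.queries) != 1:
            problems.append("exactly one query must be marked control")
        names = [q.name for q in self.queries]
        if len(set(names)) != len(names):
            problems.append("query names must be unique")
        for q in self.queries:
            problems.extend(q.validate())
        return problems

    @property
    def control_query(self) -> str:
        return next(q.name for q in self.queries if q.control)


@dataclass
class Config:
    """Top-level run configuration (analysis thresholds + simulation block)."""

    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    linkage_window: int = DEFAULT_LINKAGE_WINDOW
    min_fraction: float = DEFAULT_MIN_FRACTION
    enrichment_fdr: float = DEFAULT_ENRICHMENT_FDR
    reference: str | None = None     # reference mutant for allele comparisons
    simulation: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> list[str]:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append("alpha must lie in (0, 1)")
        if not 0 < self.enrichment_fdr < 1:
            problems.append("enrichment_fdr must lie in (0, 1)")
        if self.linkage_window < 0:
            problems.append("linkage_window must be >= 0")
        if not 0 <= self.min_fraction < 1:
            problems.append("min_fraction must lie in [0, 1)")
        problems.extend(self.simulation.validate())
        return problems

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SCALAR_TYPES = {int: (int,), float: (int, float), str: (str,), bool: (bool,)}


def _coerce_fields(cls, data: dict, path: str, problems: list[str]) -> dict:
    import dataclasses

    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            problems.append(f"unknown key '{path}{key}'")
            continue
        kwargs[key] = value
    return kwargs


def config_from_dict(data: dict[str, Any]) -> Config:
    """Build and validate a :class:`Config` from a plain mapping.

    All problems (unknown keys, type errors, invariant violations) are
    collected and reported together in a single :class:`ConfigError`.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    problems: list[str] = []
    top = _coerce_fields(Config, data, "", problems)
    sim_data = top.pop("simulation", None)
    if sim_data is not None:
        if not isinstance(sim_data, dict):
            problems.append("'simulation' must be a mapping")
            sim_data = {}
        sim_kwargs = _coerce_fields(SimConfig, sim_data, "simulation.", problems)
        queries = sim_kwargs.pop("queries", None)
        if queries is not None:
            parsed = []
            for i, q in enumerate(queries):
                if not isinstance(q, dict):
                    problems.append(f"simulation.queries[{i}] must be a mapping")
                    continue
                qk = _coerce_fields(QuerySpec, q, f"simulation.queries[{i}].", problems)
                try:
                    parsed.append(QuerySpec(**qk))
                except TypeError as exc:
                    problems.append(f"simulation.queries[{i}]: {exc}")
            sim_kwargs["queries"] = parsed
        try:
            top["simulation"] = SimConfig(**sim_kwargs)
        except TypeError as exc:
            problems.append(f"simulation: {exc}")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    cfg = Config(**top)
    problems = cfg.validate()
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    return cfg
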