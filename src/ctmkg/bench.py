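"""Linear-scalability benchmark of the graph-generation pipeline.

For hour counts h = 2^0 .. 2^e the benchmark generates a synthetic
fixture, converts it to a knowledge graph, and records individual count,
triple count, serialized byte size and wall time.  Three ordinary
least-squares fits summarize the scaling: time ~ individuals,
bytes ~ individuals and time ~ bytes.  Generation is exactly linear in
the row count, so the individual count follows the closed form
(2S+3)*h*M and the bytes~individuals fit is expected to be essentially
perfect; wall-clock fits are hardware-dependent and reported
informatively.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from scipy import stats

from .ingest import build_forecast_table
from .mapping import default_ruleset, generate_graph, serialize_graph
from .ontology import build_ontology
from .synthetic import DEFAULT_SPECIES, DomainSpec, FieldSpec, make_municipalities, simulate_fields

__all__ = ["FitResult", "BenchRun", "BenchResult", "fit_line", "run_benchmark"]


@dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float
    pvalue: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r2": self.r2, "pvalue": self.pvalue}


@dataclass
class BenchRun:
    h: int
    individuals: int
    triples: int
    nbytes: int
    seconds: float  # mean wall time over reps


@dataclass
class BenchResult:
    runs: list[BenchRun] = field(default_factory=list)
    fits: dict[str, FitResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "runs": [vars(r) for r in self.runs],
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
        }


def fit_line(x, y) -> FitResult:
    """Ordinary least squares y = slope*x + intercept with R^2 and p-value."""
    res = stats.linregress(x, y)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue) ** 2, pvalue=float(res.pvalue))


def run_benchmark(
    h_max_exponent: int = 7,
    n_municipalities: int = 45,
    n_species: int = 9,
    seed: int = 0,
    reps: int = 5,
    serialization: str = "turtle",
) -> BenchResult:
    """Run the doubling study h = 1, 2, 4, ..., 2^h_max_exponent.

    ``reps`` repeats the timed section (generation + serialization) per h
    and keeps the mean; counts and bytes are identical across reps.
    """
    if h_max_exponent < 0 or h_max_exponent > 10:
        raise ValueError("h_max_exponent must be in [0, 10]")
    species = tuple(DEFAULT_SPECIES[:n_species])
    ontology = build_ontology(species=list(species))
    rules = default_ruleset(ontology)
    domain = DomainSpec(seed=seed, n_municipalities=n_municipalities)
    municipalities = make_municipalities(domain)

    result = BenchResult()
    for exp in range(h_max_exponent + 1):
        h = 2 ** exp
        fields = simulate_fields(domain, FieldSpec(hours=h, species=species))
        table = build_forecast_table(fields, municipalities)
        times = []
        kg = None
        payload = b""
        for _ in range(max(1, reps)):
            t0 = time.perf_counter()
            kg = generate_graph(table, rules, ontology)
            payload = serialize_graph(kg, serialization)
            times.append(time.perf_counter() - t0)
        result.runs.append(
            BenchRun(
                h=h,
                individuals=kg.n_individuals,
                triples=kg.n_triples,
                nbytes=len(payload),
                seconds=sum(times) / len(times),
            )
        )

    ind = [r.individuals for r in result.runs]
    result.fits["time_vs_individuals"] = fit_line(ind, [r.seconds for r in result.runs])
    result.fits["bytes_vs_individuals"] = fit_line(ind, [r.nbytes for r in result.runs])
    result.fits["time_vs_bytes"] = fit_line(
        [r.nbytes for r in result.runs], [r.seconds for r in result.runs]
    )
    return result
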