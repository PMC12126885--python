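"""Structural quality metrics for an OWL class graph.

Nineteen metrics in the OQuaRE tradition, computed from the class
hierarchy, the properties and the annotations of an
:class:`~ctmkg.ontology.OntologyModel`.  The published one-line
definitions underdetermine several metrics (what counts as a
"relationship" vs a "property"; whether the implicit root ``owl:Thing``
participates; how the *2 variants differ), and existing implementations
disagree, so the exact operationalization used here is written down
metric-by-metric in ``docs/oquare_metrics.md``; the *2 variants use
explicitly documented alternative denominators.

Conventions used throughout (see the reference document):

* ``n``      named classes (Thing excluded);
* ``E``      all direct subclass edges including the implicit edge from
  each root class to Thing; ``E'`` excludes edges to Thing;
* ``P``      declared object + data properties;
* ``attrs(c)`` data properties with ``c`` in their domain, ``rel(c)``
  object properties with domain ``c``;
* ``depth(c)`` longest subclass chain from ``c`` up to Thing (a direct
  child of Thing has depth 1).

Ratio metrics (PROnto, RROnto) are fractions in [0, 1].  CROnto is the
mean number of instances per class and is 0 for the unpopulated template
ontology by design.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

from .ontology import OntologyModel

__all__ = ["MetricReport", "compute_metrics", "METRIC_NAMES"]

METRIC_NAMES = [
    "ANOnto", "AROnto", "CBOOnto", "CBOnto2", "CROnto", "DITOnto", "INROnto",
    "LCOMOnto", "NACOnto", "NOCOnto", "NOMOnto", "RFCOnto", "PROnto",
    "TMOnto", "TMOnto2", "POnto", "RROnto", "WMCOnto", "WMCOnto2",
]


@dataclass
class MetricReport:
    ANOnto: float
    AROnto: float
    CBOOnto: float
    CBOnto2: float
    CROnto: float
    DITOnto: float
    INROnto: float
    LCOMOnto: float
    NACOnto: float
    NOCOnto: float
    NOMOnto: float
    RFCOnto: float
    PROnto: float
    TMOnto: float
    TMOnto2: float
    POnto: float
    RROnto: float
    WMCOnto: float
    WMCOnto2: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def compute_metrics(model: OntologyModel, instances: dict[str, int] | None = None) -> MetricReport:
    """Compute all 19 metrics; ``instances`` (class -> individual count)
    feeds CROnto and defaults to an unpopulated ontology."""
    classes = list(model.classes)
    n = len(classes)
    if n == 0:
        raise ValueError("empty ontology: no classes to measure")

    named_parents = {c: list(model.classes[c].parents) for c in classes}
    # every root class has the implicit parent Thing
    ptot = {c: (len(ps) if ps else 1) for c, ps in named_parents.items()}
    e_all = sum(ptot.values())
    e_named = sum(len(ps) for ps in named_parents.values())

    children: dict[str, list[str]] = {c: [] for c in classes}
    for c, ps in named_parents.items():
        for p in ps:
            children[p].append(c)
    leaves = [c for c in classes if not children[c]]
    internal = [c for c in classes if children[c]]

    depth = {c: model.depth(c) for c in classes}

    op = list(model.object_properties.values())
    dp = list(model.data_properties.values())
    n_props = len(op) + len(dp)
    attrs = {c: sum(1 for d in dp if c in d.domains) for c in classes}
    rel = {c: sum(1 for o in op if o.domain == c) for c in classes}
    ann = {c: len(model.classes[c].annotations) for c in classes}
    inst = instances or {}

    with_named_parent = [c for c in classes if named_parents[c]]

    def mean(vals) -> float:
        vals = list(vals)
        return sum(vals) / len(vals) if vals else 0.0

    def rfc(c: str) -> int:
        reachable = {c} | model.ancestors(c)
        usable = sum(1 for o in op if o.domain in reachable) + sum(
            1 for d in dp if reachable & set(d.domains)
        )
        return usable + len(named_parents[c])

    return MetricReport(
        ANOnto=mean(ann.values()),
        AROnto=mean(attrs.values()),
        CBOOnto=(e_named / len(with_named_parent)) if with_named_parent else 0.0,
        CBOnto2=e_named / n,
        CROnto=mean(inst.get(c, 0) for c in classes),
        DITOnto=float(max(depth.values())),
        INROnto=(e_named + sum(rel.values())) / n,
        LCOMOnto=mean(depth[c] for c in leaves),
        NACOnto=mean(ptot[c] for c in leaves),
        NOCOnto=(e_named / len(internal)) if internal else 0.0,
        NOMOnto=mean(attrs[c] + rel[c] for c in classes),
        RFCOnto=mean(rfc(c) for c in classes),
        PROnto=e_all / (e_all + n_props) if (e_all + n_props) else 0.0,
        TMOnto=mean(ptot.values()),
        TMOnto2=(sum(len(ps) for ps in named_parents.values()) / len(with_named_parent))
        if with_named_parent else 0.0,
        POnto=mean(len(model.ancestors(c)) + 1 for c in classes),
        RROnto=n_props / (e_all + n_props) if (e_all + n_props) else 0.0,
        WMCOnto=mean(attrs[c] + rel[c] + ptot[c] for c in classes),
        WMCOnto2=(sum(attrs[c] + rel[c] + ptot[c] for c in classes) / len(leaves))
        if leaves else 0.0,
    )
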