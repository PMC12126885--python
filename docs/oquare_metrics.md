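# Ontology metric operationalization

Published one-line definitions of these structural metrics leave several
choices open (what counts as a "relationship" versus a "property",
whether the implicit root participates, how the `*2` variants differ),
and existing implementations disagree.  This document fixes the exact
formulas `ctmkg.metrics.compute_metrics` uses.  An independent
second implementation over adjacency lists (networkx) verifies every
formula in the test suite.

## Symbols

| symbol | meaning |
|---|---|
| `C`, `n` | named classes (the implicit root `Thing` excluded); `n = |C|` |
| `parents(c)` | direct *named* parents of `c` |
| `ptot(c)` | `|parents(c)|`, or 1 if empty (the implicit `Thing` parent) |
| `E` | all direct subclass edges incl. root→Thing; `|E| = Σ ptot(c)` |
| `E'` | subclass edges between named classes only |
| `L` | leaf classes (no named children); `I` = classes with ≥1 named child |
| `depth(c)` | longest subclass chain from `c` to Thing (child of Thing = 1) |
| `OP`, `DP`, `P` | object properties, data properties, `P = OP ∪ DP` |
| `attrs(c)` | data properties with `c` among their domains |
| `rel(c)` | object properties with domain `c` |
| `ann(c)` | annotations on `c` (label, comment, cross-references) |
| `anc(c)` | named ancestors of `c` (transitive) |
| `inst(c)` | individuals directly asserted to `c` (0 for the template) |

## Formulas

| metric | formula | notes |
|---|---|---|
| ANOnto | `Σ ann(c) / n` | mean annotations per class |
| AROnto | `Σ attrs(c) / n` | mean attributes (data properties) per class |
| CBOOnto | `|E'| / |{c : parents(c) ≠ ∅}|` | mean named parents among classes that have one; Thing links excluded |
| CBOnto2 | `|E'| / n` | variant: denominator is all classes |
| CROnto | `Σ inst(c) / n` | mean individuals per class; 0 when unpopulated |
| DITOnto | `max_c depth(c)` | longest root-to-leaf path, in edges |
| INROnto | `(|E'| + Σ rel(c)) / n` | mean relationships (subclass links + object-property usages) per class |
| LCOMOnto | `mean_{c∈L} depth(c)` | mean leaf depth (path length to Thing) |
| NACOnto | `mean_{c∈L} ptot(c)` | mean direct superclasses per leaf |
| NOCOnto | `|E'| / |I|` | mean direct named subclasses per parent class |
| NOMOnto | `Σ (attrs(c) + rel(c)) / n` | mean properties per class |
| RFCOnto | `mean_c (|{p ∈ P : dom(p) ∩ ({c} ∪ anc(c)) ≠ ∅}| + |parents(c)|)` | properties usable from the class (own or inherited) plus direct named parents |
| PROnto | `|E| / (|E| + |P|)` | share of subclass links among links+properties; fraction in [0,1] |
| TMOnto | `Σ ptot(c) / n` | mean parents per class, counting the Thing parent |
| TMOnto2 | `Σ |parents(c)| / |{c : parents(c) ≠ ∅}|` | variant: named parents only, among classes having one |
| POnto | `Σ (|anc(c)| + 1) / n` | mean ancestors per class, counting Thing |
| RROnto | `|P| / (|E| + |P|)` | share of properties among links+properties; fraction in [0,1] |
| WMCOnto | `Σ (attrs(c) + rel(c) + ptot(c)) / n` | mean properties + relationships per class |
| WMCOnto2 | `Σ (attrs(c) + rel(c) + ptot(c)) / |L|` | variant: normalized per leaf class |

## Worked values for the shipped ontology

Default nine-species ontology: 20 named classes, 6 object properties,
4 data properties, 2 annotations per class, no individuals.  Selected
values (all computed, not asserted, by the reporting path):
`ANOnto = 2.0`, `DITOnto = 4` (ChemicalEntity → Nanoparticle → PM10 →
PM2.5), `PROnto = 2/3`, `RROnto = 1/3`, `CROnto = 0`.
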