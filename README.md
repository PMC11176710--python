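# bnglcartoon

Cartoon visualization of rule-based models written in the BioNetGen
language (BNGL).

Rule-based modeling describes biochemistry as templates over multi-site
molecules rather than as an enumerated reaction network: a molecule is a
named container with binding/modification sites, each site can carry an
internal state and a bond, and reaction rules rewrite partial patterns.
The BNGL scripting syntax is compact but hard to read — an expression like

```
egf(r!1).egfr(ecd!1,tmd!+,Y1068~u,Y1148!?)
```

says that the ligand `egf` is bound through its site `r` to the receptor
ectodomain `ecd` (shared bond label `!1`), that the transmembrane site
`tmd` must be bound to *some* unspecified partner (`!+`), that tyrosine
`Y1068` is unphosphorylated (`~u`) and unbound (no bond token), and that
`Y1148`'s binding status is unknown (`!?`). `bnglcartoon` parses whole
BNGL files and draws every molecule type, seed species, observable and
reaction rule as an SVG cartoon in the VCell-style notation: molecules are
rounded boxes, sites are circles on the lower edge, explicit bonds are
arcs, `!+` is a vertical tick, `!?` a question mark, states are lettered
square badges — and, crucially, sites a rule does *not* mention are drawn
as grey shapes, making the rule's actual footprint visible. The VCell
compartment dialect (`@EC:` pattern prefixes) renders volumes as labelled
regions and membranes as bars; cBNGL site-level compartments are detected
and reported as unsupported.

It is intended for modelers and readers of rule-based-model papers who
want to understand a supplementary `.bngl` file without learning the
scripting language, and for annotating models on the web: the HTML report
is a static single page, and per-element SVGs drop into figures.

## Worked example

```python
from bnglcartoon import parse_model, parse_rule, resolve_pattern

doc = parse_model("""\
begin molecule types
  egfr(ecd,tmd,Y1068~u~p,Y1148~u~p)
end molecule types
""")
rule = parse_rule("egfr(tmd!+,Y1068~u) -> egfr(tmd!+,Y1068~p) k1")
(mol,) = resolve_pattern(rule.reactants[0], doc.molecule_types)
for site in mol.sites:
    print(site.name, "participates" if site.participating else "grey")
```

prints

```
ecd grey
tmd participates
Y1068 participates
Y1148 grey
```

— the phosphorylation rule constrains only the transmembrane site (which
must be bound) and the tyrosine whose state flips; the ectodomain and the
other tyrosine are irrelevant to it and will be greyed in the cartoon.
The same resolution drives the drawing:

```python
from bnglcartoon import layout_rule, render_svg
svg = render_svg(layout_rule(rule, doc.molecule_types), theme="dark")
open("phos.svg", "w").write(svg.xml_text)
```

From a shell, the bundled CLI ties the whole pipeline together:

```sh
bnglcartoon render model.bngl -o model.html --theme dark   # one-page report
bnglcartoon render model.bngl --format svg -o svgs/        # per-element SVGs
bnglcartoon lint model.bngl --format tsv                   # diagnostics only
bnglcartoon fixtures --seed 7 -o synthetic.bngl            # synthetic model
```

Exit codes: 0 clean, 1 diagnostics reported, 2 parse failure or (with
`--strict`) error-severity diagnostics.

Colors are deterministic: the fill hue of every molecule and site is the
FNV-1a 32-bit hash of its name modulo 360, so the same name is always the
same color, across elements, documents, themes and runs.

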