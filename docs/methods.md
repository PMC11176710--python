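# Methods

## The visual semantics

The tool renders BNGL site-graph patterns in the VCell-style cartoon
notation. The mapping from surface syntax to glyphs is exact and
one-to-one:

| syntax | meaning | glyph |
| --- | --- | --- |
| `Mol(...)` | molecule occurrence | rounded box, name-hashed fill |
| `a`, `b`, … | site | circle on the box's lower edge, declared order |
| `!n` (twice) | explicit bond | arc routed below the boxes joining the two anchors |
| `!+` | bound to an unspecified partner | short vertical tick from the site |
| `!?` | binding status unknown | question mark at the site |
| no bond token | unbound | nothing |
| `~s` | fixed internal state | square badge with the state letters |
| site not written | unconstrained | plain grey circle, no badge, no mark |

The last row carries the main information content: BNGL rules omit every
site that does not constrain them, so the cartoon shows *all* declared
sites and greys the omitted ones. Participation is decided purely by
whether the site token occurs in the written pattern. A site written with
`!?` is therefore drawn with a question mark while a truly omitted site is
grey — the two are semantically close but the distinction in the source
survives into the drawing. An explicitly written site with no bond token
means "unbound", which is also a constraint and renders in color.

A molecule-type card (the "full description") shows every declared site
with one stacked badge per allowed state, so the state vocabulary of each
site is visible at a glance.

Resolution uses the molecule-types block when present. When it is absent
or truncated — common in supplementary files — greying falls back to the
union of sites observed for that molecule name anywhere in the document
(the site census), and finally to the written sites alone. Duplicate site
names (multivalent molecules) match positionally: the first unused
declared slot with that name takes the written token. Non-participating
sites are drawn as a bare grey shape without their allowed-state badges;
showing the state list on grey sites would visually equate them with
constrained sites.

Observable patterns are resolved and greyed exactly like rule patterns,
for visual consistency.

## Compartments

Two compartment conventions exist in the BioNetGen ecosystem. The VCell
dialect tags each reactant/product pattern with `@NAME:`; it is fully
supported, both as a per-pattern prefix and as a per-side prefix
(`@EC: A() + B() -> ...`), which is normalized to per-pattern at parse
time. Volumetric compartments (dimension 3) draw as dashed labelled
regions enclosing their pattern; membranes (dimension 2) draw as a
horizontal bar through the molecule row. A reference to an undeclared
compartment is drawn as written with a warning. The cBNGL extension,
which attaches compartments to individual molecules or sites, is *not*
supported: it is detected (`dialect = cbngl_detected`), reported as an
error-severity diagnostic, and fatal only in strict mode.

## Parsing and serialization

The parser is a hand-written tokenizer/recursive-descent pass over the
block structure: blocks are case-insensitive, `begin species` and
`begin seed species` are synonyms, `\` continues a line, `#` comments
attach to the element on the same line or to the next element when on
their own line. Parameters and actions are parsed and retained but are
non-visual; unrecognized blocks are kept as raw text with a warning.
Every element records its 1-based source line. Identifiers are opaque:
no fuzzy matching, no cross-name validation beyond the lint codes below —
the model is visualized as written.

The serializer emits canonical BNGL (normalized block order, one element
per line, comments as own-line comments immediately before their element)
chosen so that parse ∘ serialize ∘ parse ≡ parse; document equality
ignores line numbers but compares all structure, comments and dialect.
The round-trip property is enforced over generated models in the tests.

Strictness is split deliberately: the standalone `parse_pattern` /
`parse_rule` functions raise on unpaired bond labels and wrong rate
counts, while `parse_model` parses leniently and leaves those findings to
`lint_model`, so a faulty model can still be displayed (errors prevent
rendering only in strict mode).

## Diagnostics

`lint_model` never raises and is deterministic; the list is sorted by
line. Codes: `observable-missing-type`, `unpaired-bond-label` (error),
`undeclared-site-in-pattern`, `cbngl-unsupported` (error),
`reversible-rule-rate-count` (error), `state-not-in-allowed-states`,
`duplicate-site-name`, `seed-species-underspecified`,
`undeclared-compartment`, `unrecognized-block`. This is intentionally a
light linter, not a validator: no mass conservation, no rate-expression
evaluation, no network generation.

## Geometry and color

All glyph dimensions live in one style table (`layout.STYLE`), in abstract
pixel units with the origin top-left and y increasing downward; the exact
constants (box height 40, site pitch 34, site radius 8, badge 14, …) are
this package's own choices, fixed so layouts are bit-identical across
runs and golden-testable via the one-shape-per-line debug format. Bond
arcs route below the molecule row, shallowest span first, deepening by a
fixed step per additional arc; crossings are permitted on dense patterns.
Long complexes extend horizontally (no wrapping) — SVG viewers scroll,
and patterns beyond four or five molecules are rare in practice.

Fill hue is `FNV-1a-32(name) mod 360` with fixed per-class saturation and
lightness; FNV-1a was chosen because it is published, trivial to
re-implement in any language, and spreads short identifiers well. Site
colors hash the site name alone, so `Y1068` matches across molecules.
Grey elements bypass the hash: `#9e9e9e` (light theme) / `#6e6e6e`
(dark). Dark mode inverts background, text and line colors only —
geometry attributes and name-hashed hues are invariant under theme
change, which the tests check by XML diff. Each layout shape maps to
exactly one SVG element (composites use a single `<g>`), so element
counts are predictable from the plan.

## The synthetic-model generator

Property tests and the acceptance script need many structurally valid
models without shipping model files. `generate_model` builds one
deterministically from a seed: by default 3 molecule types with up to 4
sites and up to 2 states per site, 3 seed species, 4 rules (40%
reversible), 2 observables, and a 25% chance of the VCell compartment
dialect with an EC/M/CP (extracellular / membrane / cytoplasm) hierarchy
— the shape of a small signaling model. Bond labels are assigned pairwise
by construction, so fault-free output lints clean by design; the `fault`
switch injects exactly one defect (`unpaired_bond`,
`missing_observable_type`, `undeclared_site`) at a recorded line for
fault-injection oracles. Names come from a fixed pronounceable pool so
rendered examples read naturally.

What the generator does not emulate: biological plausibility, rate-law
realism, large multi-molecule complexes, energy patterns, or the long
tail of dialect quirks in hand-written files. Passing tests therefore
demonstrate grammatical and structural correctness of the pipeline, not
robustness to every published model in the wild.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use 200 generator seeds for
the round-trip and bond-census properties, 50 for fault injection, 1000
random names for color stability, and 20 models × 2 themes for output
validity; each model is small (seconds for the whole suite), which is
ample for properties that are structural rather than statistical.
Coordinates are emitted with `%g` formatting; there is no floating-point
accumulation to speak of, and determinism is exact, not approximate.

## Known limitations

- cBNGL is detected but not visualized.
- No global model view (rule-interaction or contact-map graph); the page
  visualizes elements independently.
- Rate expressions are carried as opaque text; a rate referencing an
  undeclared parameter is not flagged.
- Layout is fixed-grid, not optimized; dense bond patterns may cross.
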