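"""SVG and HTML emission with deterministic name-hash coloring.

Molecules and sites are colored by hashing their name with FNV-1a (32-bit,
over the UTF-8 bytes) and taking the hash modulo 360 as an HSL hue, so two
elements that share a name are always the same color — across runs,
platforms and documents.  Saturation and lightness are fixed per element
class; grey (non-participating) elements bypass the hash entirely and use
the theme's grey.

The dark theme inverts background and text colors but leaves the
name-hashed hues untouched, so geometry and identity coloring are
invariant under theme change.  All output is built from plain string
templates and is byte-stable for identical inputs.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from xml.sax.saxutils import escape, quoteattr

from .layout import (
    LayoutPlan,
    Shape,
    layout_molecule_type,
    layout_observable,
    layout_rule_compartments,
    layout_species,
)
from .parser import ModelDocument, serialize_pattern
from .semantics import lint_model, molecule_site_census, resolve_pattern

__all__ = [
    "Color",
    "SvgDocument",
    "fnv1a_32",
    "color_for_name",
    "render_svg",
    "render_model_page",
    "THEMES",
]

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193


def fnv1a_32(data: bytes) -> int:
    """FNV-1a 32-bit hash (offset basis 2166136261, prime 16777619)."""
    h = _FNV_OFFSET
    for byte in data:
        h = ((h ^ byte) * _FNV_PRIME) & 0xFFFFFFFF
    return h


@dataclass(frozen=True)
class Color:
    """An HSL color fully determined by the hashed name."""

    hue: int  # degrees in [0, 360)
    saturation: int  # percent
    lightness: int  # percent

    def css(self) -> str:
        return f"hsl({self.hue},{self.saturation}%,{self.lightness}%)"


# saturation/lightness per element class; hue always comes from the name
_CLASS_SL = {
    "molecule": (58, 74),
    "site": (68, 62),
    "compartment": (45, 55),
    "membrane": (45, 48),
}


def color_for_name(name: str, element_class: str = "molecule") -> Color:
    """Deterministic color for a named element: hue = FNV-1a-32(name) mod
    360, saturation/lightness fixed per class.  Empty names are an error;
    grey elements never go through this map."""
    if not name:
        raise ValueError("cannot derive a color from an empty name")
    sat, light = _CLASS_SL.get(element_class, _CLASS_SL["molecule"])
    return Color(fnv1a_32(name.encode("utf-8")) % 360, sat, light)


THEMES = {
    "light": {
        "background": "#ffffff",
        "text": "#1a1a1a",
        "line": "#333333",
        "grey": "#9e9e9e",
        "badge_fill": "#fdfdfd",
    },
    "dark": {
        "background": "#1e1e1e",
        "text": "#e8e8e8",
        "line": "#cccccc",
        "grey": "#6e6e6e",
        "badge_fill": "#2e2e2e",
    },
}


@dataclass(frozen=True)
class SvgDocument:
    xml_text: str
    width: float
    height: float


def _n(v: float) -> str:
    """Stable compact number formatting for geometry attributes."""
    return f"{v:g}"


def _shape_svg(s: Shape, theme: dict[str, str]) -> str:
    """Exactly one SVG element (possibly a <g>) per shape."""
    grey = theme["grey"]
    line = theme["line"]
    text_fill = theme["text"]
    if s.kind == "molecule_box":
        fill = grey if s.grey else color_for_name(s.text or "?", "molecule").css()
        return (
            f'<rect x={quoteattr(_n(s.x))} y={quoteattr(_n(s.y))} '
            f'width={quoteattr(_n(s.w))} height={quoteattr(_n(s.h))} '
            f'rx={quoteattr(_n(min(10.0, s.h / 4)))} fill={quoteattr(fill)} '
            f'stroke={quoteattr(line)} stroke-width="1"/>'
        )
    if s.kind == "site_glyph":
        fill = grey if s.grey else color_for_name(s.text or "?", "site").css()
        cx, cy, r = s.x + s.w / 2, s.y + s.h / 2, s.w / 2
        return (
            f'<circle cx={quoteattr(_n(cx))} cy={quoteattr(_n(cy))} r={quoteattr(_n(r))} '
            f'fill={quoteattr(fill)} stroke={quoteattr(line)} stroke-width="1"/>'
        )
    if s.kind == "state_badge":
        tx, ty = s.x + s.w / 2, s.y + s.h - 3.5
        return (
            f'<g><rect x={quoteattr(_n(s.x))} y={quoteattr(_n(s.y))} '
            f'width={quoteattr(_n(s.w))} height={quoteattr(_n(s.h))} '
            f'fill={quoteattr(theme["badge_fill"])} stroke={quoteattr(line)} stroke-width="1"/>'
            f'<text x={quoteattr(_n(tx))} y={quoteattr(_n(ty))} font-size="9" '
            f'text-anchor="middle" fill={quoteattr(text_fill)}>{escape(s.text or "")}</text></g>'
        )
    if s.kind == "bond_line":
        (x1, y1), (x2, y2) = s.points
        yd = s.y + s.h
        d = f"M {_n(x1)} {_n(y1)} L {_n(x1)} {_n(yd)} L {_n(x2)} {_n(yd)} L {_n(x2)} {_n(y2)}"
        return (
            f'<path d={quoteattr(d)} fill="none" stroke={quoteattr(line)} '
            f'stroke-width="1.2"/>'
        )
    if s.kind == "bound_any_tick":
        return (
            f'<line x1={quoteattr(_n(s.x))} y1={quoteattr(_n(s.y))} '
            f'x2={quoteattr(_n(s.x))} y2={quoteattr(_n(s.y + s.h))} '
            f'stroke={quoteattr(line)} stroke-width="2"/>'
        )
    if s.kind == "unknown_mark":
        return (
            f'<text x={quoteattr(_n(s.x + s.w / 2))} y={quoteattr(_n(s.y + s.h - 2))} '
            f'font-size="11" text-anchor="middle" font-weight="bold" '
            f'fill={quoteattr(text_fill)}>?</text>'
        )
    if s.kind == "arrow":
        y = s.y + s.h / 2
        x1, x2 = s.x + 2, s.x + s.w - 2
        head = 6.0
        parts = [
            f'<line x1={quoteattr(_n(x1))} y1={quoteattr(_n(y))} x2={quoteattr(_n(x2))} '
            f'y2={quoteattr(_n(y))} stroke={quoteattr(line)} stroke-width="1.5"/>',
            f'<path d={quoteattr(f"M {_n(x2 - head)} {_n(y - head / 2)} L {_n(x2)} {_n(y)} L {_n(x2 - head)} {_n(y + head / 2)}")} '
            f'fill="none" stroke={quoteattr(line)} stroke-width="1.5"/>',
        ]
        if s.style_ref == "double":
            parts.append(
                f'<path d={quoteattr(f"M {_n(x1 + head)} {_n(y - head / 2)} L {_n(x1)} {_n(y)} L {_n(x1 + head)} {_n(y + head / 2)}")} '
                f'fill="none" stroke={quoteattr(line)} stroke-width="1.5"/>'
            )
        return "<g>" + "".join(parts) + "</g>"
    if s.kind == "plus_sign":
        return (
            f'<text x={quoteattr(_n(s.x + s.w / 2))} y={quoteattr(_n(s.y + s.h - 2))} '
            f'font-size="14" text-anchor="middle" fill={quoteattr(text_fill)}>+</text>'
        )
    if s.kind == "compartment_region":
        stroke = color_for_name(s.text or "?", "compartment").css()
        return (
            f'<rect x={quoteattr(_n(s.x))} y={quoteattr(_n(s.y))} '
            f'width={quoteattr(_n(s.w))} height={quoteattr(_n(s.h))} rx="12" '
            f'fill="none" stroke={quoteattr(stroke)} stroke-width="1.5" '
            f'stroke-dasharray="6 3"/>'
        )
    if s.kind == "membrane_bar":
        fill = color_for_name(s.text or "?", "membrane").css()
        return (
            f'<rect x={quoteattr(_n(s.x))} y={quoteattr(_n(s.y))} '
            f'width={quoteattr(_n(s.w))} height={quoteattr(_n(s.h))} '
            f'fill={quoteattr(fill)} stroke="none"/>'
        )
    if s.kind in ("text_label", "comment_label"):
        fill = grey if s.grey else text_fill
        size = {
            "molecule_name": 12,
            "site_name": 8,
            "compartment_name": 10,
            "rule_label": 12,
            "observable_name": 12,
            "comment": 10,
            "null_species": 14,
        }.get(s.style_ref, 10)
        style = ' font-style="italic"' if s.kind == "comment_label" else ""
        return (
            f'<text x={quoteattr(_n(s.x))} y={quoteattr(_n(s.y + s.h - 3))} '
            f'font-size="{size}"{style} fill={quoteattr(fill)}>{escape(s.text or "")}</text>'
        )
    raise ValueError(f"unknown shape kind {s.kind!r}")


def render_svg(plan: LayoutPlan, theme: str = "light") -> SvgDocument:
    """Emit one SVG 1.1 document: a background rect followed by exactly one
    element per shape, in plan order.  Byte-stable for identical inputs;
    geometry attributes are invariant under theme change."""
    th = THEMES[theme]
    w, h = _n(plan.width), _n(plan.height)
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width={quoteattr(w)} height={quoteattr(h)} '
        f'viewBox={quoteattr(f"0 0 {w} {h}")} '
        f'font-family="Helvetica,Arial,sans-serif">',
        f'<rect x="0" y="0" width={quoteattr(w)} height={quoteattr(h)} '
        f'fill={quoteattr(th["background"])}/>',
    ]
    parts.extend(_shape_svg(s, th) for s in plan.shapes)
    parts.append("</svg>")
    return SvgDocument("\n".join(parts) + "\n", plan.width, plan.height)


# ---------------------------------------------------------------------------
# Whole-model HTML page
# ---------------------------------------------------------------------------


def element_plans(doc: ModelDocument) -> list[tuple[str, int, str, LayoutPlan, tuple[str, ...]]]:
    """(block_key, 1-based index, display name, plan, comments) for every
    visual element of the document, in page order."""
    census = molecule_site_census(doc)
    types = doc.molecule_types
    out: list[tuple[str, int, str, LayoutPlan, tuple[str, ...]]] = []
    for i, mt in enumerate(doc.molecule_types):
        out.append(
            (
                "molecule_types",
                i + 1,
                mt.name,
                layout_molecule_type(mt),
                doc.comments_for("molecule_types", i),
            )
        )
    comp_dims = {c.name: c.dimension for c in doc.compartments}
    for i, sp in enumerate(doc.species):
        resolved = resolve_pattern(sp.pattern, types, census, None, sp.line)
        plan = layout_species(
            resolved,
            sp.pattern.compartment,
            comp_dims.get(sp.pattern.compartment) if sp.pattern.compartment else None,
        )
        out.append(
            (
                "species",
                i + 1,
                serialize_pattern(sp.pattern),
                plan,
                doc.comments_for("species", i),
            )
        )
    for i, obs in enumerate(doc.observables):
        plan = layout_observable(obs.name, obs.obs_type, obs.patterns, types, census)
        out.append(("observables", i + 1, obs.name, plan, doc.comments_for("observables", i)))
    for i, rule in enumerate(doc.rules):
        plan = layout_rule_compartments(
            rule, doc.compartments, types, census, doc.comments_for("rules", i)
        )
        name = rule.label or f"rule {i + 1}"
        out.append(("rules", i + 1, name, plan, doc.comments_for("rules", i)))
    return out


_SECTION_TITLES = {
    "molecule_types": "Molecule types",
    "species": "Seed species",
    "observables": "Observables",
    "rules": "Reaction rules",
}

_PAGE_CSS = """\
body { font-family: Helvetica, Arial, sans-serif; margin: 1.5em;
       background: %(background)s; color: %(text)s; }
h2 { border-bottom: 1px solid %(grey)s; padding-bottom: 0.2em; }
figure { margin: 0.8em 0; }
figcaption { font-size: 0.85em; color: %(grey)s; }
p.comment { font-style: italic; margin: 0.2em 0 0.6em 0; }
footer { margin-top: 2em; font-size: 0.85em; }
footer pre { background: rgba(128,128,128,0.12); padding: 0.5em; }
"""


def render_model_page(doc: ModelDocument, theme: str = "light") -> str:
    """A static single-page HTML report: molecule types, seed species,
    observables and reaction rules in order, each element's inline SVG
    followed by its source comments as visible text.  Parameters and
    actions are non-visual and omitted; lint diagnostics go in a footer."""
    th = THEMES[theme]
    parts = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '<meta charset="utf-8"/>',
        "<title>BNGL model cartoon</title>",
        "<style>",
        _PAGE_CSS % th,
        "</style>",
        "</head>",
        "<body>",
        "<h1>BNGL model cartoon</h1>",
    ]
    plans = element_plans(doc)
    for block in ("molecule_types", "species", "observables", "rules"):
        parts.append(f"<section id={quoteattr(block)}>")
        parts.append(f"<h2>{_html.escape(_SECTION_TITLES[block])}</h2>")
        any_el = False
        for blk, idx, name, plan, comments in plans:
            if blk != block:
                continue
            any_el = True
            svg = render_svg(plan, theme)
            parts.append("<figure>")
            # strip the XML prolog for inline embedding
            parts.append(svg.xml_text.split("\n", 1)[1].rstrip())
            parts.append(f"<figcaption>{_html.escape(name)}</figcaption>")
            parts.append("</figure>")
            for c in comments:
                parts.append(f'<p class="comment"># {_html.escape(c)}</p>')
        if not any_el:
            parts.append("<p>(none)</p>")
        parts.append("</section>")
    diags = lint_model(doc)
    parts.append("<footer>")
    parts.append("<h2>Diagnostics</h2>")
    if diags:
        lines = "\n".join(
            f"{d.severity}: line {d.line}: {d.message} [{d.code}]" for d in diags
        )
        parts.append(f"<pre>{_html.escape(lines)}</pre>")
    else:
        parts.append("<p>No diagnostics.</p>")
    parts.append("</footer>")
    parts.append("</body>")
    parts.append("</html>")
    return "\n".join(parts) + "\n"
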