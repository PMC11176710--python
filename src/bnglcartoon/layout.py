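"""Deterministic cartoon geometry for resolved patterns, rules and types.

Coordinate convention: origin top-left, y increases downward, abstract
pixel units, half-open boxes.  Every glyph dimension lives in the
:data:`STYLE` table so golden tests have stable numbers; identical input
always yields a bit-identical :class:`LayoutPlan`.

Glyph vocabulary (matching the VCell-style cartoon notation):

* a molecule is a rounded box with its name, sites strung in declared
  order along the lower edge as small circles;
* a numeric bond (``!n``) is an arc routed below the boxes connecting its
  two site anchors;
* ``!+`` ("must be bound to something") is a short vertical tick hanging
  from the site;
* ``!?`` (binding unknown) is a small question mark at the site;
* a fixed internal state (``~u``) is a square badge with the state letters
  under the site; a molecule-type card stacks one badge per allowed state;
* sites not participating in a rule are drawn as plain grey shapes with no
  badge or bond mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .parser import (
    UNBOUND,
    UNSPECIFIED,
    CompartmentDef,
    Diagnostic,
    MoleculeTypeDef,
    ReactionRule,
)
from .semantics import ResolvedMolecule, ResolvedSite, resolve_pattern

__all__ = [
    "STYLE",
    "Shape",
    "LayoutPlan",
    "layout_species",
    "layout_rule",
    "layout_rule_compartments",
    "layout_molecule_type",
    "layout_observable",
]

# All lengths in abstract pixels.  One table so goldens stay stable.
STYLE = {
    "margin": 12.0,  # outer margin around every plan
    "mol_gap": 26.0,  # horizontal gap between molecule boxes in one pattern
    "mol_h": 40.0,  # molecule box height
    "mol_min_w": 64.0,  # molecule box minimum width
    "mol_rx": 10.0,  # box corner radius
    "site_r": 8.0,  # site glyph radius
    "site_pitch": 34.0,  # spacing between site centres
    "site_pad": 20.0,  # box edge to first site centre
    "badge": 14.0,  # state badge side length
    "badge_gap": 3.0,  # vertical gap between stacked badges
    "tick_len": 11.0,  # '!+' vertical tick length
    "mark_h": 13.0,  # '?' mark nominal box
    "bond_gap": 24.0,  # anchor row to shallowest bond arc
    "bond_step": 8.0,  # extra depth per additional bond arc
    "arrow_w": 54.0,  # reaction arrow width
    "arrow_h": 12.0,
    "plus_w": 16.0,  # '+' separator nominal box
    "tile_gap": 18.0,  # gap between pattern tiles in a rule
    "char_w": 7.0,  # crude monospace text-width estimate
    "label_h": 14.0,  # text label height
    "comment_h": 12.0,
    "frame_pad": 14.0,  # compartment region padding
    "membrane_h": 7.0,  # membrane bar thickness
}

_S = STYLE  # local alias


@dataclass(frozen=True)
class Shape:
    """One drawable primitive; ``(x, y, w, h)`` is its bounding box.

    ``points`` carries the two site anchors for ``bond_line``; ``text`` the
    label string (also the colour-hash key for named elements);
    ``style_ref`` a style-class identifier consumed by the renderer.
    """

    kind: str
    x: float
    y: float
    w: float
    h: float
    grey: bool = False
    style_ref: str = ""
    text: str | None = None
    points: tuple[tuple[float, float], ...] = ()

    def debug_line(self) -> str:
        return (
            f"{self.kind} {self.x:g} {self.y:g} {self.w:g} {self.h:g} "
            f"{int(self.grey)} {self.style_ref}"
        )


@dataclass
class LayoutPlan:
    shapes: list[Shape] = field(default_factory=list)
    width: float = 0.0
    height: float = 0.0
    anchors: dict[tuple[int, int, int], tuple[float, float]] = field(default_factory=dict)
    diagnostics: list[Diagnostic] = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for s in self.shapes if s.kind == kind)

    def to_debug(self) -> str:
        """One shape per line: ``kind x y w h grey style_ref``."""
        return "\n".join(s.debug_line() for s in self.shapes)


def _text_w(text: str) -> float:
    return _S["char_w"] * len(text)


def _translate(plan: LayoutPlan, dx: float, dy: float) -> LayoutPlan:
    shapes = [
        replace(
            s,
            x=s.x + dx,
            y=s.y + dy,
            points=tuple((px + dx, py + dy) for px, py in s.points),
        )
        for s in plan.shapes
    ]
    anchors = {k: (x + dx, y + dy) for k, (x, y) in plan.anchors.items()}
    return LayoutPlan(shapes, plan.width, plan.height, anchors, list(plan.diagnostics))


# ---------------------------------------------------------------------------
# Species / pattern cores
# ---------------------------------------------------------------------------


def _molecule_width(mol: ResolvedMolecule) -> float:
    n = len(mol.sites)
    span = 2 * _S["site_pad"] + (n - 1) * _S["site_pitch"] if n else 0.0
    return max(_S["mol_min_w"], span, _text_w(mol.name) + 16.0)


def _species_core(molecules: list[ResolvedMolecule], stack_states: bool = False) -> LayoutPlan:
    """Lay one connected pattern out at origin (no outer margin).

    ``stack_states`` draws every allowed state as a badge stack (the
    molecule-type card view) instead of the single written-state badge.
    """
    plan = LayoutPlan()
    x = 0.0
    box_bottom = _S["mol_h"]
    below = 0.0  # deepest extent below the box bottom, before bond arcs
    bond_ends: dict[int, list[tuple[float, float]]] = {}
    r = _S["site_r"]
    for mi, mol in enumerate(molecules):
        w = _molecule_width(mol)
        plan.shapes.append(Shape("molecule_box", x, 0.0, w, _S["mol_h"], False, "molecule", mol.name))
        plan.shapes.append(
            Shape(
                "text_label",
                x + w / 2 - _text_w(mol.name) / 2,
                4.0,
                _text_w(mol.name),
                _S["label_h"],
                False,
                "molecule_name",
                mol.name,
            )
        )
        for si, site in enumerate(mol.sites):
            sx = x + _S["site_pad"] + si * _S["site_pitch"]
            cy = box_bottom
            grey = not site.participating
            plan.shapes.append(
                Shape("site_glyph", sx - r, cy - r, 2 * r, 2 * r, grey, "site", site.name)
            )
            lw = min(_text_w(site.name), _S["site_pitch"] + 2.0)
            plan.shapes.append(
                Shape(
                    "text_label",
                    max(x + 1.0, sx - lw / 2),
                    cy - r - _S["label_h"] - 1.0,
                    lw,
                    _S["label_h"],
                    grey,
                    "site_name",
                    site.name,
                )
            )
            plan.anchors[(0, mi, si)] = (sx, cy + r)
            if stack_states:
                by = cy + r + 3.0
                for state in site.allowed_states:
                    plan.shapes.append(
                        Shape(
                            "state_badge",
                            sx - _S["badge"] / 2,
                            by,
                            _S["badge"],
                            _S["badge"],
                            False,
                            "state",
                            state,
                        )
                    )
                    by += _S["badge"] + _S["badge_gap"]
                below = max(below, by - box_bottom)
                continue
            if not site.participating:
                continue
            if site.state.kind == "named":
                plan.shapes.append(
                    Shape(
                        "state_badge",
                        sx - _S["badge"] / 2,
                        cy + r + 3.0,
                        _S["badge"],
                        _S["badge"],
                        False,
                        "state",
                        site.state.state,
                    )
                )
                below = max(below, r + 3.0 + _S["badge"])
            if site.bond.kind == "bound_any":
                plan.shapes.append(
                    Shape("bound_any_tick", sx, cy + r, 0.0, _S["tick_len"], False, "bond")
                )
                below = max(below, r + _S["tick_len"])
            elif site.bond.kind == "unknown":
                plan.shapes.append(
                    Shape(
                        "unknown_mark",
                        sx - 4.0,
                        cy + r + 2.0,
                        8.0,
                        _S["mark_h"],
                        False,
                        "bond",
                        "?",
                    )
                )
                below = max(below, r + 2.0 + _S["mark_h"])
            elif site.bond.kind == "labeled":
                bond_ends.setdefault(site.bond.label, []).append((sx, cy + r))
        x += w + _S["mol_gap"]

    width = x - _S["mol_gap"] if molecules else 0.0
    # bond arcs below everything else, shallow spans first
    paired = sorted(
        ((lbl, pts) for lbl, pts in bond_ends.items() if len(pts) == 2),
        key=lambda item: (abs(item[1][0][0] - item[1][1][0]), item[0]),
    )
    depth_y = box_bottom + _S["bond_gap"]
    for i, (lbl, pts) in enumerate(paired):
        (x1, y1), (x2, y2) = sorted(pts)
        dy = depth_y + i * _S["bond_step"]
        plan.shapes.append(
            Shape(
                "bond_line",
                x1,
                min(y1, y2),
                x2 - x1,
                dy - min(y1, y2),
                False,
                f"bond_{lbl}",
                str(lbl),
                ((x1, y1), (x2, y2)),
            )
        )
        below = max(below, dy - box_bottom)
    if not molecules:
        # the null species '0'
        plan.shapes.append(
            Shape("text_label", 0.0, _S["mol_h"] / 2 - _S["label_h"] / 2, _S["char_w"], _S["label_h"], False, "null_species", "0")
        )
        width = _S["char_w"]
    plan.width = width
    plan.height = box_bottom + below
    return plan


def _frame_compartment(
    core: LayoutPlan, name: str, dimension: int | None
) -> LayoutPlan:
    """Wrap a pattern core in its compartment framing.

    Volumetric (3D, or undeclared) compartments are labelled rounded
    regions enclosing the pattern; membranes (2D) are a horizontal bar
    through the anchored molecules with the name at the right end.
    """
    pad = _S["frame_pad"]
    if dimension == 2:
        bar_y = _S["mol_h"] - _S["membrane_h"] / 2
        plan = _translate(core, 0.0, _S["label_h"])
        bar = Shape(
            "membrane_bar",
            -pad / 2,
            bar_y + _S["label_h"],
            core.width + pad,
            _S["membrane_h"],
            False,
            "membrane",
            name,
        )
        label = Shape(
            "text_label", -pad / 2, 0.0, _text_w(name), _S["label_h"], False, "compartment_name", name
        )
        plan.shapes.insert(0, bar)
        plan.shapes.insert(0, label)
        plan = _translate(plan, pad / 2, 0.0)
        plan.width = core.width + pad
        plan.height = core.height + _S["label_h"]
        return plan
    plan = _translate(core, pad, pad + _S["label_h"])
    region = Shape(
        "compartment_region",
        0.0,
        0.0,
        core.width + 2 * pad,
        core.height + 2 * pad + _S["label_h"],
        False,
        "compartment",
        name,
    )
    label = Shape(
        "text_label", pad / 2, 3.0, _text_w(name), _S["label_h"], False, "compartment_name", name
    )
    plan.shapes.insert(0, region)
    plan.shapes.insert(1, label)
    plan.width = region.w
    plan.height = region.h
    return plan


def _finish(plan: LayoutPlan, header: float = 0.0) -> LayoutPlan:
    m = _S["margin"]
    out = _translate(plan, m, m + header)
    out.width = plan.width + 2 * m
    out.height = plan.height + 2 * m + header
    return out


def layout_species(
    molecules: list[ResolvedMolecule],
    compartment: str | None = None,
    compartment_dimension: int | None = None,
) -> LayoutPlan:
    """Lay out one species pattern: molecule boxes left-to-right in pattern
    order, sites along the lower edge, labelled bonds as arcs below the
    boxes, ``!+`` ticks, ``!?`` marks, state badges, and grey propagated
    from non-participating sites.  ``compartment`` adds region framing."""
    core = _species_core(molecules)
    if compartment:
        core = _frame_compartment(core, compartment, compartment_dimension)
    return _finish(core)


def layout_molecule_type(mtype: MoleculeTypeDef) -> LayoutPlan:
    """The molecule-type card: every declared site with a stacked badge per
    allowed state (the full description of the molecule)."""
    resolved = ResolvedMolecule(
        mtype.name,
        tuple(
            ResolvedSite(s.name, True, state=UNSPECIFIED, bond=UNBOUND, allowed_states=s.allowed_states)
            for s in mtype.sites
        ),
    )
    return _finish(_species_core([resolved], stack_states=True))


def _hstack(tiles: list[LayoutPlan | Shape]) -> LayoutPlan:
    """Stack pattern tiles and separator glyphs left to right, top-aligned,
    re-keying anchors by tile index."""
    out = LayoutPlan()
    x = 0.0
    group = 0
    for tile in tiles:
        if isinstance(tile, Shape):
            out.shapes.append(replace(tile, x=tile.x + x))
            x += tile.w + _S["tile_gap"]
            continue
        moved = _translate(tile, x, 0.0)
        out.shapes.extend(moved.shapes)
        for (_, mi, si), pt in moved.anchors.items():
            out.anchors[(group, mi, si)] = pt
        out.diagnostics.extend(moved.diagnostics)
        out.height = max(out.height, tile.height)
        x += tile.width + _S["tile_gap"]
        group += 1
    out.width = max(0.0, x - _S["tile_gap"])
    return out


def _rule_header(rule: ReactionRule, comments: tuple[str, ...]) -> list[Shape]:
    shapes: list[Shape] = []
    y = 0.0
    if rule.label:
        shapes.append(
            Shape("text_label", 0.0, y, _text_w(rule.label), _S["label_h"], False, "rule_label", rule.label)
        )
        y += _S["label_h"]
    for c in comments:
        shapes.append(
            Shape("comment_label", 0.0, y, _text_w(c), _S["comment_h"], False, "comment", c)
        )
        y += _S["comment_h"]
    return shapes


def _layout_rule_impl(
    rule: ReactionRule,
    types: list[MoleculeTypeDef],
    compartments: list[CompartmentDef] | None,
    census: dict[str, tuple[str, ...]] | None,
    comments: tuple[str, ...],
) -> LayoutPlan:
    comp_dims = {c.name: c.dimension for c in (compartments or [])}
    declared = {c.name for c in (compartments or [])}
    diags: list[Diagnostic] = []

    def tile_for(pattern) -> LayoutPlan:
        resolved = resolve_pattern(pattern, types, census, None, rule.line)
        core = _species_core(resolved)
        if compartments is not None and pattern.compartment:
            name = pattern.compartment
            if name not in declared:
                diags.append(
                    Diagnostic(
                        "warning",
                        "undeclared-compartment",
                        f"compartment {name!r} is not declared",
                        rule.line,
                    )
                )
            core = _frame_compartment(core, name, comp_dims.get(name))
        return core

    mid_y = _S["mol_h"] / 2
    plus = Shape(
        "plus_sign", 0.0, mid_y - _S["label_h"] / 2, _S["plus_w"], _S["label_h"], False, "plus", "+"
    )
    arrow = Shape(
        "arrow",
        0.0,
        mid_y - _S["arrow_h"] / 2,
        _S["arrow_w"],
        _S["arrow_h"],
        False,
        "double" if rule.reversible else "single",
    )
    tiles: list[LayoutPlan | Shape] = []
    for i, pat in enumerate(rule.reactants):
        if i:
            tiles.append(plus)
        tiles.append(tile_for(pat))
    tiles.append(arrow)
    for i, pat in enumerate(rule.products):
        if i:
            tiles.append(plus)
        tiles.append(tile_for(pat))
    body = _hstack(tiles)
    body.diagnostics.extend(diags)

    header = _rule_header(rule, comments)
    header_h = sum(_S["label_h"] if s.kind == "text_label" else _S["comment_h"] for s in header)
    plan = _finish(body, header=header_h)
    m = _S["margin"]
    plan.shapes = [replace(s, x=s.x + m, y=s.y + m) for s in header] + plan.shapes
    plan.width = max(plan.width, max((m * 2 + s.x + s.w for s in header), default=0.0))
    return plan


def layout_rule(
    rule: ReactionRule,
    types: list[MoleculeTypeDef],
    census: dict[str, tuple[str, ...]] | None = None,
    comments: tuple[str, ...] = (),
) -> LayoutPlan:
    """Reactant tiles left, arrow centre (double-headed when reversible),
    product tiles right, ``+`` between siblings; label and comments above.
    Rate expressions are non-visual and never drawn."""
    return _layout_rule_impl(rule, types, None, census, comments)


def layout_rule_compartments(
    rule: ReactionRule,
    compartments: list[CompartmentDef],
    types: list[MoleculeTypeDef],
    census: dict[str, tuple[str, ...]] | None = None,
    comments: tuple[str, ...] = (),
) -> LayoutPlan:
    """Like :func:`layout_rule` but with VCell compartment framing: each
    compartment-tagged pattern is enclosed in a labelled volumetric region
    or anchored to a membrane bar.  A rule with no compartment annotations
    lays out identically to :func:`layout_rule`; an undeclared compartment
    name draws as written with a warning in ``plan.diagnostics``."""
    if not any(c is not None for c in rule.reactant_compartments + rule.product_compartments):
        return layout_rule(rule, types, census, comments)
    return _layout_rule_impl(rule, types, compartments, census, comments)


def layout_observable(
    name: str,
    obs_type: str,
    patterns,
    types: list[MoleculeTypeDef],
    census: dict[str, tuple[str, ...]] | None = None,
    comments: tuple[str, ...] = (),
) -> LayoutPlan:
    """An observable card: its name/type heading above its pattern tiles."""
    tiles: list[LayoutPlan | Shape] = []
    for pat in patterns:
        resolved = resolve_pattern(pat, types, census, None, 0)
        core = _species_core(resolved)
        if pat.compartment:
            core = _frame_compartment(core, pat.compartment, None)
        tiles.append(core)
    body = _hstack(tiles) if tiles else LayoutPlan()
    title = name if obs_type == "missing" else f"{name} ({obs_type.capitalize()})"
    header = Shape(
        "text_label", 0.0, 0.0, _text_w(title), _S["label_h"], False, "observable_name", title
    )
    plan = _finish(body, header=_S["label_h"])
    m = _S["margin"]
    plan.shapes.insert(0, replace(header, x=header.x + m, y=header.y + m))
    plan.width = max(plan.width, 2 * m + header.w)
    return plan
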