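"""Pattern resolution and model linting.

BNGL rules omit every site that does not constrain the rule.  The cartoon
convention is the opposite: every declared site of a molecule is drawn, and
sites *not* written in the pattern are shown as grey shapes so the reader
can see at a glance which sites participate.  :func:`resolve_pattern`
computes that participation flag by matching each molecule occurrence
against its molecule-type declaration (or, when the molecule-types block is
absent, against the union of sites observed for that molecule name anywhere
in the document — see :func:`molecule_site_census`).

:func:`lint_model` produces the tool's light diagnostics: unpaired bond
labels, observables with no declared type, sites or states not present in
the molecule-type declaration, bad rate counts, and the unsupported-dialect
flags recorded at parse time.  It never raises; rendering proceeds on
warnings and, outside strict mode, on errors too — the model is visualized
as written.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parser import (
    BOND_UNKNOWN,
    UNSPECIFIED,
    BondSpec,
    Diagnostic,
    MoleculePattern,
    MoleculeTypeDef,
    ModelDocument,
    SpeciesPattern,
    StateSpec,
)

__all__ = [
    "Diagnostic",
    "ResolvedSite",
    "ResolvedMolecule",
    "resolve_pattern",
    "lint_model",
    "molecule_site_census",
    "diagnostics_report",
]


@dataclass(frozen=True)
class ResolvedSite:
    """One drawn site: ``participating`` is True iff the site token was
    written explicitly in the pattern; non-participating sites carry no
    state/bond information (they render as plain grey glyphs)."""

    name: str
    participating: bool
    state: StateSpec
    bond: BondSpec
    allowed_states: tuple[str, ...] = ()


@dataclass(frozen=True)
class ResolvedMolecule:
    name: str
    sites: tuple[ResolvedSite, ...]


def _resolve_molecule(
    mol: MoleculePattern,
    declared: list[tuple[str, tuple[str, ...]]],
    diagnostics: list[Diagnostic] | None,
    line: int,
) -> ResolvedMolecule:
    """Match written sites to declared slots; duplicates match positionally
    (first unused declared slot with that name)."""
    used = [False] * len(declared)
    assignment: dict[int, int] = {}  # declared slot -> written site index
    extras: list[int] = []
    for wi, sp in enumerate(mol.sites):
        slot = next(
            (j for j, (nm, _) in enumerate(declared) if not used[j] and nm == sp.name), None
        )
        if slot is None:
            extras.append(wi)
            if diagnostics is not None:
                diagnostics.append(
                    Diagnostic(
                        "warning",
                        "undeclared-site-in-pattern",
                        f"site {sp.name!r} is not declared on molecule {mol.name!r}",
                        line,
                    )
                )
        else:
            used[slot] = True
            assignment[slot] = wi
    sites: list[ResolvedSite] = []
    for j, (nm, states) in enumerate(declared):
        if j in assignment:
            sp = mol.sites[assignment[j]]
            sites.append(ResolvedSite(nm, True, sp.state, sp.bond, states))
        else:
            sites.append(ResolvedSite(nm, False, UNSPECIFIED, BOND_UNKNOWN, states))
    for wi in extras:
        sp = mol.sites[wi]
        sites.append(ResolvedSite(sp.name, True, sp.state, sp.bond, ()))
    return ResolvedMolecule(mol.name, tuple(sites))


def resolve_pattern(
    pattern: SpeciesPattern,
    types: list[MoleculeTypeDef],
    census: dict[str, tuple[str, ...]] | None = None,
    diagnostics: list[Diagnostic] | None = None,
    line: int = 0,
) -> list[ResolvedMolecule]:
    """Resolve each molecule of ``pattern`` to its full drawn site list.

    When a :class:`MoleculeTypeDef` exists for a molecule name, the result
    carries exactly the declared sites in declared order (plus any written
    but undeclared sites appended at the end, each with a warning appended
    to ``diagnostics`` when given).  Without a declaration, the site list
    falls back to the document-wide ``census`` for that molecule name, or
    to the written sites alone.
    """
    by_name: dict[str, MoleculeTypeDef] = {}
    for mt in types:
        by_name.setdefault(mt.name, mt)
    resolved: list[ResolvedMolecule] = []
    for mol in pattern.molecules:
        mt = by_name.get(mol.name)
        if mt is not None:
            declared = [(s.name, s.allowed_states) for s in mt.sites]
            resolved.append(_resolve_molecule(mol, declared, diagnostics, line))
        elif census and mol.name in census:
            declared = [(nm, ()) for nm in census[mol.name]]
            resolved.append(_resolve_molecule(mol, declared, None, line))
        else:
            resolved.append(
                ResolvedMolecule(
                    mol.name,
                    tuple(
                        ResolvedSite(s.name, True, s.state, s.bond, ()) for s in mol.sites
                    ),
                )
            )
    return resolved


def molecule_site_census(doc: ModelDocument) -> dict[str, tuple[str, ...]]:
    """Union of site names observed per molecule name across all blocks, in
    deterministic first-seen order.  Supports greying when the
    molecule-types block is absent or truncated."""
    census: dict[str, dict[str, None]] = {}

    def see(name: str, site_names) -> None:
        slot = census.setdefault(name, {})
        for s in site_names:
            slot.setdefault(s, None)

    for mt in doc.molecule_types:
        see(mt.name, (s.name for s in mt.sites))
    for pat in _all_patterns(doc):
        for mol in pat.molecules:
            see(mol.name, (s.name for s in mol.sites))
    return {name: tuple(sites) for name, sites in census.items()}


def _all_patterns(doc: ModelDocument):
    for sp in doc.species:
        yield sp.pattern
    for obs in doc.observables:
        yield from obs.patterns
    for rule in doc.rules:
        yield from rule.reactants
        yield from rule.products


def _pattern_holders(doc: ModelDocument):
    """(pattern, source line) for every pattern in the document."""
    for sp in doc.species:
        yield sp.pattern, sp.line
    for obs in doc.observables:
        for pat in obs.patterns:
            yield pat, obs.line
    for rule in doc.rules:
        for pat in rule.reactants + rule.products:
            yield pat, rule.line


def lint_model(doc: ModelDocument) -> list[Diagnostic]:
    """Light diagnostics over a parsed document; never raises.

    Emitted codes: ``observable-missing-type`` (warning),
    ``unpaired-bond-label`` (error), ``undeclared-site-in-pattern``
    (warning), ``cbngl-unsupported`` (error),
    ``reversible-rule-rate-count`` (error), ``state-not-in-allowed-states``
    (warning), ``duplicate-site-name`` (warning),
    ``undeclared-compartment`` (warning), plus any parse-time findings.
    The list is sorted by line (stably, so same-line order is emission
    order).
    """
    diags: list[Diagnostic] = list(doc.parse_diagnostics)

    for mt in doc.molecule_types:
        names = [s.name for s in mt.sites]
        for nm in sorted(set(n for n in names if names.count(n) > 1)):
            diags.append(
                Diagnostic(
                    "warning",
                    "duplicate-site-name",
                    f"molecule type {mt.name!r} declares site {nm!r} more than once "
                    "(pattern sites match positionally)",
                    mt.line,
                )
            )

    for obs in doc.observables:
        if obs.obs_type == "missing":
            diags.append(
                Diagnostic(
                    "warning",
                    "observable-missing-type",
                    f"observable {obs.name!r} has no defined type (Molecules or Species)",
                    obs.line,
                )
            )

    for pat, line in _pattern_holders(doc):
        for label in pat.unpaired_bond_labels():
            diags.append(
                Diagnostic(
                    "error",
                    "unpaired-bond-label",
                    f"bond label {label} must appear exactly twice within one pattern",
                    line,
                )
            )

    by_name: dict[str, MoleculeTypeDef] = {}
    for mt in doc.molecule_types:
        by_name.setdefault(mt.name, mt)
    for pat, line in _pattern_holders(doc):
        for mol in pat.molecules:
            mt = by_name.get(mol.name)
            if mt is None:
                continue
            declared = [(s.name, s.allowed_states) for s in mt.sites]
            site_diags: list[Diagnostic] = []
            resolved = _resolve_molecule(mol, declared, site_diags, line)
            diags.extend(site_diags)
            for rs in resolved.sites:
                if (
                    rs.participating
                    and rs.state.kind == "named"
                    and rs.allowed_states
                    and rs.state.state not in rs.allowed_states
                ):
                    diags.append(
                        Diagnostic(
                            "warning",
                            "state-not-in-allowed-states",
                            f"state {rs.state.state!r} of site {rs.name!r} is not among "
                            f"the allowed states of {mol.name!r} "
                            f"({', '.join(rs.allowed_states)})",
                            line,
                        )
                    )

    # seed species should be concrete: no wildcard bonds, and a state on
    # every site that declares allowed states
    for sp in doc.species:
        vague: list[str] = []
        for mol in sp.pattern.molecules:
            mt = by_name.get(mol.name)
            declared_states = {s.name: s.allowed_states for s in mt.sites} if mt else {}
            written = {s.name for s in mol.sites}
            for s in mol.sites:
                if s.bond.kind in ("bound_any", "unknown"):
                    vague.append(f"{mol.name}.{s.name} has wildcard bond {s.bond.token()}")
                elif declared_states.get(s.name) and s.state.kind == "unspecified":
                    vague.append(f"{mol.name}.{s.name} has no state")
            if mt:
                for sd in mt.sites:
                    if sd.name not in written:
                        vague.append(f"{mol.name}.{sd.name} is omitted")
        if vague:
            diags.append(
                Diagnostic(
                    "warning",
                    "seed-species-underspecified",
                    "seed species is not fully specified: " + "; ".join(vague),
                    sp.line,
                )
            )

    for rule in doc.rules:
        want = 2 if rule.reversible else 1
        if len(rule.rates) != want:
            kind = "reversible" if rule.reversible else "irreversible"
            diags.append(
                Diagnostic(
                    "error",
                    "reversible-rule-rate-count",
                    f"{kind} rule requires {want} rate expression(s), found {len(rule.rates)}",
                    rule.line,
                )
            )

    declared_comps = {c.name for c in doc.compartments}
    for pat, line in _pattern_holders(doc):
        if pat.compartment and doc.compartments and pat.compartment not in declared_comps:
            diags.append(
                Diagnostic(
                    "warning",
                    "undeclared-compartment",
                    f"compartment {pat.compartment!r} is not declared",
                    line,
                )
            )

    diags.sort(key=lambda d: d.line)
    return diags


def diagnostics_report(diags: list[Diagnostic], fmt: str = "text") -> str:
    """Render diagnostics as a human-readable report or machine-readable
    ``severity<TAB>code<TAB>line<TAB>message`` lines."""
    if fmt == "tsv":
        return "\n".join(d.as_tsv() for d in diags)
    return "\n".join(f"{d.severity}: line {d.line}: {d.message} [{d.code}]" for d in diags)
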