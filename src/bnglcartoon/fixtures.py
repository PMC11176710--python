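"""Seeded random generator of valid (and deliberately faulty) BNGL models.

Property tests need a stream of structurally valid models covering the
whole pattern grammar — every bond kind (``!n``, ``!+``, ``!?``, unbound),
both state kinds, reversible and irreversible rules, compartment tags —
without shipping any model files.  :func:`generate_model` builds such a
model deterministically from a seed: identical parameters always yield
identical text.  Bond labels are assigned pairwise by construction, so
fault-free output lints clean; the ``fault`` switch injects exactly one
known defect at a recorded line for fault-injection oracles.

Names come from a fixed pronounceable pool so rendered examples stay
readable.  The generator makes no claim of biological plausibility — it
exercises the grammar, not biochemistry.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

__all__ = ["FixtureParams", "GeneratedModel", "generate_model", "generate_model_info"]

_MOL_POOL = ["Lig", "Rec", "Kin", "Phos", "Adap", "Scaf", "Gef", "Gap", "Sos", "Grb"]
_SITE_POOL = ["a", "b", "c", "d", "y1", "y2", "s1", "s2", "sh2", "pdz"]
_STATE_POOL = ["u", "p", "on", "off", "open", "closed"]

FAULTS = ("unpaired_bond", "missing_observable_type", "undeclared_site")


@dataclass
class FixtureParams:
    """Knobs of the generator; counts are sizes, probabilities in [0,1]."""

    seed: int = 0
    n_molecule_types: int = 3
    max_sites: int = 4
    max_states: int = 2
    n_species: int = 3
    n_rules: int = 4
    n_observables: int = 2
    p_reversible: float = 0.4
    p_compartmental: float = 0.25
    fault: str | None = None

    def __post_init__(self) -> None:
        for f in ("n_molecule_types", "max_sites", "max_states", "n_species", "n_rules", "n_observables"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("p_reversible", "p_compartmental"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.fault is not None and self.fault not in FAULTS:
            raise ValueError(f"unknown fault {self.fault!r}; choose from {FAULTS}")


@dataclass
class GeneratedModel:
    """Generated text plus the bookkeeping fault-injection oracles need."""

    text: str
    fault: str | None = None
    fault_line: int | None = None  # 1-based line of the injected defect


@dataclass
class _MolSpec:
    name: str
    sites: list[tuple[str, tuple[str, ...]]]


def _site_token(rng: random.Random, site: tuple[str, tuple[str, ...]], bond: str = "") -> str:
    """One written site token with a random state choice (or none)."""
    name, states = site
    state = ""
    if states and rng.random() < 0.7:
        state = f"~{rng.choice(states)}"
    return f"{name}{state}{bond}"


def _pattern_text(
    rng: random.Random,
    mols: list[_MolSpec],
    compartment: str | None,
    allow_wildcards: bool,
) -> str:
    """A pattern over 1–2 molecules; any numeric bond label is used exactly
    twice (pairing by construction)."""
    n_mols = 2 if len(mols) >= 1 and rng.random() < 0.35 else 1
    chosen = [rng.choice(mols) for _ in range(n_mols)]
    mol_sites: list[list[str]] = []
    bonded: list[tuple[int, tuple[str, tuple[str, ...]]]] = []
    for mi, spec in enumerate(chosen):
        k = rng.randint(0, len(spec.sites)) if spec.sites else 0
        picked = spec.sites[:k]  # declared-order subset
        tokens = []
        for site in picked:
            bond = ""
            if allow_wildcards and rng.random() < 0.25:
                bond = rng.choice(["!+", "!?"])
            tokens.append(_site_token(rng, site, bond))
        mol_sites.append(tokens)
        if spec.sites and len(picked) < len(spec.sites):
            bonded.append((mi, spec.sites[len(picked)]))
    # connect two molecules with a paired label through one extra site each
    if n_mols == 2 and len(bonded) == 2:
        label = rng.randint(1, 4)
        for mi, site in bonded:
            mol_sites[mi].append(f"{site[0]}!{label}")
    body = ".".join(
        f"{spec.name}({','.join(tokens)})" for spec, tokens in zip(chosen, mol_sites)
    )
    if compartment:
        return f"@{compartment}:{body}"
    return body


def generate_model_info(params: FixtureParams) -> GeneratedModel:
    """Like :func:`generate_model` but also reports the injected fault line."""
    rng = random.Random(params.seed)
    lines: list[str] = []
    fault_line: int | None = None

    mols: list[_MolSpec] = []
    for i in range(params.n_molecule_types):
        name = _MOL_POOL[i % len(_MOL_POOL)] + ("" if i < len(_MOL_POOL) else str(i))
        n_sites = rng.randint(0, params.max_sites)
        site_names = rng.sample(_SITE_POOL, min(n_sites, len(_SITE_POOL)))
        sites = []
        for sn in site_names:
            if params.max_states >= 2 and rng.random() < 0.5:
                k = rng.randint(2, max(2, params.max_states))
                states = tuple(rng.sample(_STATE_POOL, min(k, len(_STATE_POOL))))
            else:
                states = ()
            sites.append((sn, states))
        mols.append(_MolSpec(name, sites))

    compartmental = bool(mols) and rng.random() < params.p_compartmental
    comp_of = (lambda: rng.choice(["EC", "M", "CP"])) if compartmental else (lambda: None)

    n_rules = params.n_rules
    lines.append("begin parameters")
    for i in range(n_rules):
        lines.append(f"  kf{i + 1} {rng.randint(1, 100)}")
        lines.append(f"  kr{i + 1} 0.{rng.randint(1, 9)}")
    lines.append("  A0 100")
    lines.append("end parameters")
    lines.append("")

    if compartmental:
        lines.append("begin compartments")
        lines.append("  EC 3 1000000")
        lines.append("  M 2 1 EC")
        lines.append("  CP 3 100000 M")
        lines.append("end compartments")
        lines.append("")

    if mols:
        lines.append("begin molecule types")
        for i, spec in enumerate(mols):
            body = ",".join(sn + "".join(f"~{s}" for s in states) for sn, states in spec.sites)
            comment = "  # generated molecule type" if rng.random() < 0.3 else ""
            lines.append(f"  {spec.name}({body}){comment}")
        lines.append("end molecule types")
        lines.append("")

    if mols and params.n_species:
        lines.append("begin seed species")
        for i in range(params.n_species):
            spec = rng.choice(mols)
            # seed species are fully specified: every site written, a concrete
            # state where one is declared, no wildcards
            tokens = [
                sn + (f"~{states[0]}" if states else "") for sn, states in spec.sites
            ]
            pat = f"{spec.name}({','.join(tokens)})"
            comp = comp_of()
            if comp:
                pat = f"@{comp}:{pat}"
            amount = rng.choice(["A0", str(rng.randint(1, 500))])
            lines.append(f"  {pat} {amount}")
        lines.append("end seed species")
        lines.append("")

    if mols and (params.n_observables or params.fault == "missing_observable_type"):
        lines.append("begin observables")
        for i in range(params.n_observables):
            kind = rng.choice(["Molecules", "Species"])
            pat = _pattern_text(rng, mols, comp_of(), allow_wildcards=True)
            comment = "  # tracked quantity" if rng.random() < 0.3 else ""
            lines.append(f"  {kind} Obs{i + 1} {pat}{comment}")
        if params.fault == "missing_observable_type":
            pat = _pattern_text(rng, mols, None, allow_wildcards=False)
            lines.append(f"  ObsX {pat}")
            fault_line = len(lines)
        lines.append("end observables")
        lines.append("")

    if mols and (n_rules or params.fault in ("unpaired_bond", "undeclared_site")):
        lines.append("begin reaction rules")
        for i in range(n_rules):
            reversible = rng.random() < params.p_reversible
            kind = rng.choice(["state_change", "binding"])
            if len(mols) < 2:
                kind = "state_change"
            comp = comp_of()
            if kind == "binding":
                a, b = rng.sample(mols, 2)
                if not (a.sites and b.sites):
                    kind = "state_change"
                else:
                    sa, sb = a.sites[0], b.sites[0]
                    lhs = f"{a.name}({sa[0]}) + {b.name}({sb[0]})"
                    rhs = f"{a.name}({sa[0]}!1).{b.name}({sb[0]}!1)"
                    if comp:
                        lhs = f"@EC:{a.name}({sa[0]}) + @M:{b.name}({sb[0]})"
                        rhs = f"@M:{a.name}({sa[0]}!1).{b.name}({sb[0]}!1)"
            if kind == "state_change":
                spec = rng.choice([m for m in mols if any(s[1] for s in m.sites)] or mols)
                stateful = [s for s in spec.sites if s[1]]
                if stateful:
                    sn, states = stateful[0]
                    extra = ""
                    if len(spec.sites) > 1 and rng.random() < 0.5:
                        other = next(s for s in spec.sites if s[0] != sn)
                        extra = f",{other[0]}!+" if rng.random() < 0.5 else f",{other[0]}!?"
                        extra_r = extra
                    else:
                        extra_r = extra
                    lhs = f"{spec.name}({sn}~{states[0]}{extra})"
                    rhs = f"{spec.name}({sn}~{states[-1]}{extra_r})"
                else:
                    lhs = f"{spec.name}()"
                    rhs = f"{spec.name}()"
                if comp:
                    lhs = f"@{comp}:{lhs}"
                    rhs = f"@{comp}:{rhs}"
            arrow = "<->" if reversible else "->"
            rates = f"kf{i + 1}, kr{i + 1}" if reversible else f"kf{i + 1}"
            label = f"R{i + 1}: " if rng.random() < 0.5 else ""
            comment = "  # generated rule" if rng.random() < 0.3 else ""
            lines.append(f"  {label}{lhs} {arrow} {rhs} {rates}{comment}")
        if params.fault == "unpaired_bond":
            spec = next((m for m in mols if m.sites), None)
            sn = spec.sites[0][0] if spec else "a"
            name = spec.name if spec else "Lig"
            lines.append(f"  {name}({sn}!9) -> {name}({sn}) kf1")
            fault_line = len(lines)
        if params.fault == "undeclared_site":
            spec = rng.choice(mols)
            lines.append(f"  {spec.name}(zz) -> {spec.name}(zz) kf1")
            fault_line = len(lines)
        lines.append("end reaction rules")
        lines.append("")

    lines.append("generate_network({overwrite=>1})")
    text = "\n".join(lines).rstrip("\n") + "\n"
    return GeneratedModel(text, params.fault, fault_line)


def generate_model(params: FixtureParams) -> str:
    """Deterministic BNGL source for ``params`` (same seed, same text)."""
    return generate_model_info(params).text
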