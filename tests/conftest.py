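"""Shared fixtures: the canonical EGF/EGFR worked example and helpers.

The EGF/EGFR fragment is the standard didactic example for site-graph
patterns: the ligand ``egf`` binds the receptor ectodomain ``ecd`` (bond
``!1``), the transmembrane site ``tmd`` must be bound to an unspecified
partner (``!+``), tyrosine ``Y1068`` is unphosphorylated (``~u``) and
unbound, and ``Y11148``'s binding status is unknown (``!?``).
"""

from __future__ import annotations

import re

import pytest

# the canonical pattern expression (note the Y11148 spelling is kept as
# written: identifiers are opaque, no fuzzy matching)
EGF_EGFR_PATTERN = "egf(r!1).egfr(ecd!1,tmd!+,Y1068~u,Y11148!?)"

# full receptor declaration: four sites, two phospho-states per tyrosine
EGFR_TYPE = "egfr(ecd,tmd,Y1068~u~p,Y1148~u~p)"

# the phosphorylation rule: tmd must be bound for Y1068 to flip state
PHOS_RULE = "egfr(tmd!+,Y1068~u) -> egfr(tmd!+,Y1068~p) k1"

# binding across compartments: ligand in the extracellular volume (EC),
# receptor on the membrane (M), complex on the membrane
COMPARTMENT_RULE = "@EC:egf(r) + @M:egfr(ecd,tmd,Y1068~u,Y1148~u) -> @M:egf(r!1).egfr(ecd!1,tmd,Y1068~u,Y1148~u) kon"

SMALL_MODEL = f"""\
begin parameters
  k1 1e-3
  kon 0.5
end parameters
begin compartments
  EC 3 1000000
  M 2 1 EC
end compartments
begin molecule types
  egf(r)
  {EGFR_TYPE}  # the receptor
end molecule types
begin seed species
  egf(r) 500
  egfr(ecd,tmd,Y1068~u,Y1148~u) 100
end seed species
begin observables
  # phosphorylated receptor
  Molecules pY1068 egfr(Y1068~p)
end observables
begin reaction rules
  phos: {PHOS_RULE}  # receptor cross-phosphorylation
  {COMPARTMENT_RULE}
end reaction rules
generate_network({{overwrite=>1}})
"""


@pytest.fixture
def small_model_text() -> str:
    return SMALL_MODEL


@pytest.fixture
def small_model_doc(small_model_text):
    from bnglcartoon import parse_model

    return parse_model(small_model_text)


_SITE_TOKEN_RE = re.compile(
    r"[A-Za-z_][A-Za-z0-9_]*(?:~[A-Za-z0-9_]+)?(?:!(?:\d+|\+|\?))?"
)


def count_site_tokens(pattern_text: str) -> int:
    """Independent textual census of written site tokens in one pattern:
    counts comma-separated entries inside each molecule's parentheses."""
    total = 0
    for inner in re.findall(r"\(([^()]*)\)", pattern_text):
        inner = inner.strip()
        if inner:
            total += inner.count(",") + 1
    return total


def count_bond_tokens(pattern_text: str) -> tuple[int, int, int]:
    """(paired numeric labels, '!+' tokens, '!?' tokens) by pure text scan."""
    labels = re.findall(r"!(\d+)", pattern_text)
    paired = sum(1 for lbl in set(labels) if labels.count(lbl) == 2)
    return paired, pattern_text.count("!+"), pattern_text.count("!?")
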