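"""Condition vocabulary of the two-experiment study design.

Five labelled conditions are compared, drawn from an iron-limitation
experiment (strains NW305 and NW186 grown with or without Fe(II)SO4,
arginine supplemented) and a supplement experiment (NW186 with standard
arginine vs excess citrulline):

* ``NW305 ++Fe_a`` — NW305, iron replete, arginine.
* ``NW305 -Fe_a``  — NW305, iron limited, arginine.
* ``NW186 -Fe_a``  — NW186, iron limited, arginine (highest citrate
  production *rate*).
* ``NW186 +Fe_a``  — NW186, iron present, arginine.
* ``NW186 +Fe_c``  — NW186, iron present, excess citrulline (highest
  overall citrate *yield*).

Display labels contain spaces and signs, so every label has a
filesystem-safe token used in file headers and sample names
(``"NW186 -Fe_a"`` <-> ``"NW186_minusFe_a"``).
"""

from __future__ import annotations

# Display label -> filesystem-safe token (bidirectional, fixed order).
CONDITION_TOKENS: dict[str, str] = {
    "NW305 -Fe_a": "NW305_minusFe_a",
    "NW305 ++Fe_a": "NW305_plusplusFe_a",
    "NW186 -Fe_a": "NW186_minusFe_a",
    "NW186 +Fe_a": "NW186_plusFe_a",
    "NW186 +Fe_c": "NW186_plusFe_c",
}

TOKEN_CONDITIONS: dict[str, str] = {v: k for k, v in CONDITION_TOKENS.items()}

#: Canonical condition order (used for tables and generated data).
CONDITIONS: tuple[str, ...] = tuple(CONDITION_TOKENS)

#: Replicates per condition in the study design.
N_REPLICATES = 2

#: The two conditions in which a candidate must be strongly expressed
#: (highest citrate production rate / highest overall citrate yield).
KEY_CONDITIONS: tuple[str, str] = ("NW186 -Fe_a", "NW186 +Fe_c")

#: Named differential-expression contrasts, each as (test, reference).
#: C1 compares the citrate hyper-producing strain to its parent under iron
#: limitation and is the ranking contrast; C2 compares excess citrulline to
#: standard arginine within NW186; C3 compares iron limitation within NW305
#: and is advisory only (NW305 shifts to oxalate under iron limitation).
CONTRASTS: dict[str, tuple[str, str]] = {
    "C1": ("NW186 -Fe_a", "NW305 -Fe_a"),
    "C2": ("NW186 +Fe_c", "NW186 +Fe_a"),
    "C3": ("NW305 -Fe_a", "NW305 ++Fe_a"),
}

#: Contrast whose log2 fold-change orders the final shortlist.
RANKING_CONTRAST = "C1"


def token_for(condition: str) -> str:
    """Return the filesystem-safe token for a display label."""
    try:
        return CONDITION_TOKENS[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r}; valid: {sorted(CONDITION_TOKENS)}"
        ) from None


def condition_for(token: str) -> str:
    """Return the display label for a filesystem-safe token."""
    try:
        return TOKEN_CONDITIONS[token]
    except KeyError:
        raise KeyError(
            f"unknown condition token {token!r}; valid: {sorted(TOKEN_CONDITIONS)}"
        ) from None
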