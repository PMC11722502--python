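"""Chromatin-state vocabulary registry.

Maps each cell context (melanocyte / melanoma) to the state labels counted
as promoter or enhancer. Any region labelled with a promoter or enhancer
state is considered regulatory for that context.
"""

from __future__ import annotations

MELANOCYTE = "melanocyte"
MELANOMA = "melanoma"

CONTEXTS = (MELANOCYTE, MELANOMA)

#: Promoter-state labels per context.
PROMOTER_STATES: dict[str, frozenset[str]] = {
    MELANOCYTE: frozenset(
        {"PromU", "PromD1", "PromD2", "TssA", "PromP", "PromBiv", "Tx_Reg"}
    ),
    MELANOMA: frozenset({"1_TssA", "2_PromWkD", "3_TssWkP"}),
}

#: Enhancer-state labels per context; melanocyte labels pool the primary,
#: auxiliary and imputed model vocabularies.
ENHANCER_STATES: dict[str, frozenset[str]] = {
    MELANOCYTE: frozenset(
        {"Enh", "EnhG", "EnhBiv"}
        | {"EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "EnhBiv"}
        | {
            "TxEnh5",
            "TxEnh3",
            "TxEnhW",
            "EnhA1",
            "EnhA2",
            "EnhAF",
            "EnhW1",
            "EnhW2",
            "EnhAc",
        }
    ),
    MELANOMA: frozenset(
        {"4_EnhA", "5_EnhM", "6_EnhW", "7_TxEnhM", "7_TxEnhW", "9_TxWkEnhW"}
    ),
}

#: Regulatory = promoter union enhancer.
REGULATORY_STATES: dict[str, frozenset[str]] = {
    ctx: PROMOTER_STATES[ctx] | ENHANCER_STATES[ctx] for ctx in CONTEXTS
}


def is_promoter_state(label: str, context: str) -> bool:
    return label in PROMOTER_STATES[context]


def is_enhancer_state(label: str, context: str) -> bool:
    return label in ENHANCER_STATES[context]


def is_regulatory_state(label: str, context: str) -> bool:
    return label in REGULATORY_STATES[context]
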