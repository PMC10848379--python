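"""Controlled vocabulary for mitochondrial gene labels.

Metazoan mitogenomes carry a fixed cast of 37 genes — 13 protein-coding
genes (PCGs), 22 tRNAs, 2 rRNAs — plus the AT-rich control region (CR).
Different sources spell the same gene differently: feature tables use
``trnL1``/``nad4l``-style codes while gene-order figures use one-letter
tRNA abbreviations (``L1``, ``F``, ...).  This module defines one
canonical label per gene and folds every accepted alias onto it, so that
joins between annotation tables and gene-order strings cannot silently
miss.
"""

from __future__ import annotations

# feature type constants
PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"

FEATURE_TYPES = (PCG, TRNA, RRNA, CONTROL_REGION)

PCG_LABELS = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "atp6", "atp8",
)

# one-letter tRNA codes; leucine and serine each have two isoacceptors
TRNA_CODES = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)

TRNA_LABELS = tuple(f"trn{c}" for c in TRNA_CODES)
RRNA_LABELS = ("rrnS", "rrnL")
CR_LABEL = "CR"

ALL_LABELS = PCG_LABELS + TRNA_LABELS + RRNA_LABELS + (CR_LABEL,)

#: canonical label -> feature type
LABEL_TYPES: dict[str, str] = {
    **{g: PCG for g in PCG_LABELS},
    **{t: TRNA for t in TRNA_LABELS},
    **{r: RRNA for r in RRNA_LABELS},
    CR_LABEL: CONTROL_REGION,
}

# amino-acid spellings occasionally seen in strand listings / figures
_AA_NAME_TO_CODE = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F",
    "gly": "G", "his": "H", "ile": "I", "lys": "K", "met": "M",
    "asn": "N", "pro": "P", "gln": "Q", "arg": "R", "thr": "T",
    "val": "V", "trp": "W", "tyr": "Y",
}


def _build_alias_map() -> dict[str, str]:
    alias: dict[str, str] = {}
    for label in ALL_LABELS:
        alias[label.lower()] = label
    # one-letter tRNA codes (as used in gene-order strings)
    for code, label in zip(TRNA_CODES, TRNA_LABELS):
        alias[code.lower()] = label
        alias[f"trna-{code.lower()}"] = label
        alias[f"trn{code.lower()}"] = label
    for name, code in _AA_NAME_TO_CODE.items():
        alias[f"trna-{name}"] = f"trn{code}"
    # common variants
    alias["nad4l"] = "nad4l"
    alias["rrns"] = "rrnS"
    alias["rrnl"] = "rrnL"
    alias["12s"] = "rrnS"
    alias["16s"] = "rrnL"
    alias["cr"] = CR_LABEL
    alias["d-loop"] = CR_LABEL
    alias["at-rich"] = CR_LABEL
    alias["control_region"] = CR_LABEL
    return alias


_ALIASES = _build_alias_map()


class UnknownLabelError(ValueError):
    """Raised when a gene label is outside the controlled vocabulary."""


def normalize_label(raw: str) -> str:
    """Fold *raw* onto the canonical gene label.

    >>> normalize_label("nad4L")
    'nad4l'
    >>> normalize_label("L2")
    'trnL2'
    """
    key = raw.strip().lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnknownLabelError(f"unknown feature name: {raw!r}") from None


def label_type(label: str) -> str:
    """Feature type (PCG/tRNA/rRNA/control_region) of a canonical label."""
    try:
        return LABEL_TYPES[label]
    except KeyError:
        raise UnknownLabelError(f"unknown feature name: {label!r}") from None


def short_code(label: str) -> str:
    """One-letter display code for tRNAs; identity for everything else."""
    if label.startswith("trn"):
        return label[3:]
    return label
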