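"""Ordinal encoding of embryo developmental stages.

Single-frame embryo images are annotated with the morphokinetic stage at
which they were extracted: start of 2-cell (t2), 3-cell (t3), 4-cell (t4),
5-cell (t5), 8-cell (t8), 9-cell (t9), morula (tM) and full blastocyst (tB).
Because 8- and 9-cell embryos are routinely confused with one another in
clinical grading, they are merged into a single class, yielding a 7-level
ordinal coding:

    t2 -> 1, t3 -> 2, t4 -> 3, t5 -> 4, t8/t9 -> 5, tM -> 6, tB -> 7

The coding is order-preserving in developmental time, which is what makes
quadratic (squared-distance) disagreement weights meaningful.
"""

from __future__ import annotations

from .exceptions import StageParseError

#: Number of merged ordinal stage classes.
N_STAGES = 7

#: Raw annotation name -> merged ordinal code.
STAGE_CODES: dict[str, int] = {
    "t2": 1,
    "t3": 2,
    "t4": 3,
    "t5": 4,
    "t8": 5,
    "t9": 5,
    "tm": 6,
    "tb": 7,
}

#: Merged code -> canonical display name.
STAGE_NAMES: dict[int, str] = {
    1: "2-cell",
    2: "3-cell",
    3: "4-cell",
    4: "5-cell",
    5: "8/9-cell",
    6: "morula",
    7: "blastocyst",
}

ALL_CODES: tuple[int, ...] = tuple(range(1, N_STAGES + 1))


def encode_stage(label: str | int) -> int:
    """Normalise a stage label (name or code) to its merged ordinal code.

    Accepts the annotation names ``t2``..``t9``, ``tM``, ``tB`` (case
    insensitive) or integer codes 1..7 (also as digit strings). ``t8`` and
    ``t9`` both map to code 5.

    Raises
    ------
    StageParseError
        If the label is not a recognised name or code; the message names
        the offending value.
    """
    if isinstance(label, bool):
        raise StageParseError(f"unrecognised stage label: {label!r}")
    if isinstance(label, int):
        code = label
    else:
        text = str(label).strip()
        key = text.lower()
        if key in STAGE_CODES:
            return STAGE_CODES[key]
        try:
            code = int(text)
        except ValueError:
            raise StageParseError(f"unrecognised stage label: {label!r}") from None
    if code in ALL_CODES:
        return int(code)
    raise StageParseError(f"stage code out of range 1..{N_STAGES}: {label!r}")


def stage_name(code: int) -> str:
    """Human-readable name for a merged stage code."""
    try:
        return STAGE_NAMES[int(code)]
    except (KeyError, ValueError, TypeError):
        raise StageParseError(f"stage code out of range 1..{N_STAGES}: {code!r}") from None
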