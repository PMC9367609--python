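"""Naive string-scanning oracles for the repeat-context artifact rules.

Independent of the package implementation: each function works directly on
the full reference string with explicit substring checks, the way one would
verify a single variant by eye.
"""

def _first_group_len(s: str) -> int:
    n = 0
    for c in s:
        if c == s[0]:
            n += 1
        else:
            break
    return n


def _trailing_run(s: str) -> int:
    return _first_group_len(s[::-1])


def oracle_del_upstream_homopolymer(seq: str, pos: int, ref: str, alt: str, min_run: int) -> bool:
    """One-base deletion (anchor at 1-based ``pos``) upstream of a run >= min_run."""
    if not (len(ref) == 2 and len(alt) == 1):
        return False
    after = seq[pos + 1 :]  # bases 3' of the deleted base (which sits at pos+1)
    return _first_group_len(after) >= min_run


def oracle_ins_upstream_homopolymer(seq: str, pos: int, ref: str, alt: str, min_run: int) -> bool:
    """Insertion of 1-2 bases (after ``pos``) upstream of a run >= min_run."""
    if not (len(alt) > len(ref) == 1 and len(alt) - 1 in (1, 2)):
        return False
    after = seq[pos:]  # bases 3' of the insertion point
    return _first_group_len(after) >= min_run


def oracle_snv_flanking_repeat(
    seq: str, pos: int, ref: str, alt: str, min_run: int, mode: str = "either"
) -> bool:
    """SNV at ``pos`` with an adjacent homopolymer run >= min_run."""
    if not (len(ref) == len(alt) == 1):
        return False
    up = _trailing_run(seq[: pos - 1])
    down = _first_group_len(seq[pos:])
    if mode == "both":
        return up >= min_run and down >= min_run
    return up >= min_run or down >= min_run


def oracle_inframe_repeat(seq: str, pos: int, ref: str, alt: str, min_copies: int = 2) -> bool:
    """Inframe indel whose unit appears >= min_copies times adjacent to the locus."""
    if len(ref) > len(alt) == 1:
        unit = ref[1:]
        down = seq[pos + len(unit) :]
    elif len(alt) > len(ref) == 1:
        unit = alt[1:]
        down = seq[pos:]
    else:
        return False
    if len(unit) % 3 != 0 or not unit:
        return False
    up = seq[:pos]
    return up.endswith(unit * min_copies) or down.startswith(unit * min_copies)
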