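"""Minimal Praat TextGrid interval-tier reader/writer.

Supports the long ("full") and short text formats for IntervalTier
tiers; point tiers are ignored.  This covers the interchange need of the
pipeline — utterance tiers per speaker — without pulling in a dedicated
dependency.
"""

from __future__ import annotations

import re
from pathlib import Path

__all__ = ["read_textgrid", "write_textgrid"]

# interval = (xmin, xmax, text)
Tier = list[tuple[float, float, str]]


def read_textgrid(path: str | Path) -> dict[str, Tier]:
    """Read every IntervalTier of a TextGrid; returns {tier_name: intervals}."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text:
        raise ValueError(f"{path} does not look like a Praat TextGrid")
    if re.search(r"item\s*\[", text):
        return _read_long(text)
    return _read_short(text)


def _read_long(text: str) -> dict[str, Tier]:
    tiers: dict[str, Tier] = {}
    # split into item blocks after the header
    blocks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    for block in blocks:
        cls = re.search(r'class\s*=\s*"([^"]*)"', block)
        if cls is None or cls.group(1) != "IntervalTier":
            continue
        name_m = re.search(r'name\s*=\s*"([^"]*)"', block)
        name = name_m.group(1) if name_m else ""
        intervals: Tier = []
        for m in re.finditer(
                r"intervals\s*\[\d+\]\s*:\s*"
                r"xmin\s*=\s*([-\d.eE+]+)\s*"
                r"xmax\s*=\s*([-\d.eE+]+)\s*"
                r'text\s*=\s*"((?:[^"]|"")*)"', block):
            xmin, xmax = float(m.group(1)), float(m.group(2))
            label = m.group(3).replace('""', '"')
            intervals.append((xmin, xmax, label))
        tiers[name] = intervals
    return tiers


def _read_short(text: str) -> dict[str, Tier]:
    # token stream: quoted strings and bare numbers, in file order
    tokens = re.findall(r'"(?:[^"]|"")*"|[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?',
                        text)

    def unq(tok: str) -> str:
        return tok[1:-1].replace('""', '"')

    i = 0

    def next_tok() -> str:
        nonlocal i
        tok = tokens[i]
        i += 1
        return tok

    assert unq(next_tok()) == "ooTextFile"
    next_tok()  # "TextGrid"
    next_tok(), next_tok()  # global xmin, xmax
    n_tiers = int(next_tok())
    tiers: dict[str, Tier] = {}
    for _ in range(n_tiers):
        cls = unq(next_tok())
        name = unq(next_tok())
        next_tok(), next_tok()  # tier xmin, xmax
        n_items = int(next_tok())
        intervals: Tier = []
        for _ in range(n_items):
            if cls == "IntervalTier":
                xmin = float(next_tok())
                xmax = float(next_tok())
                label = unq(next_tok())
                intervals.append((xmin, xmax, label))
            else:  # TextTier point: time, mark
                next_tok(), next_tok()
        if cls == "IntervalTier":
            tiers[name] = intervals
    return tiers


def write_textgrid(tiers: dict[str, Tier], path: str | Path,
                   xmin: float | None = None, xmax: float | None = None) -> None:
    """Write interval tiers as a long-format TextGrid.

    Gaps between supplied intervals are padded with empty-text intervals
    so each tier tiles [xmin, xmax], as Praat expects.
    """
    all_iv = [iv for tier in tiers.values() for iv in tier]
    lo = 0.0 if xmin is None else xmin
    hi = (max((iv[1] for iv in all_iv), default=lo + 1.0)
          if xmax is None else xmax)

    lines = ['File type = "ooTextFile"', 'Object class = "TextGrid"', "",
             f"xmin = {lo}", f"xmax = {hi}", "tiers? <exists>",
             f"size = {len(tiers)}", "item []:"]
    for ti, (name, tier) in enumerate(tiers.items(), start=1):
        padded = _pad(sorted(tier), lo, hi)
        lines += [f"    item [{ti}]:",
                  '        class = "IntervalTier"',
                  f'        name = "{name}"',
                  f"        xmin = {lo}",
                  f"        xmax = {hi}",
                  f"        intervals: size = {len(padded)}"]
        for ii, (a, b, label) in enumerate(padded, start=1):
            esc = label.replace('"', '""')
            lines += [f"        intervals [{ii}]:",
                      f"            xmin = {a}",
                      f"            xmax = {b}",
                      f'            text = "{esc}"']
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _pad(tier: Tier, lo: float, hi: float) -> Tier:
    out: Tier = []
    cursor = lo
    for a, b, label in tier:
        if a > cursor + 1e-9:
            out.append((cursor, a, ""))
        out.append((a, b, label))
        cursor = b
    if cursor < hi - 1e-9:
        out.append((cursor, hi, ""))
    return out
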