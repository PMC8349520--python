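"""TNT-dialect and NEXUS serialization of combined character matrices.

The TNT dialect covers exactly what the placement analyses need: an
``xread`` block with a ``&[cont]`` section (continuous cells as single
values or ``lo-hi`` ranges) followed by a ``&[num]`` section (discrete
cells, polymorphism in square brackets), and a ``ccode`` line flagging
ordered discrete characters.  Character indices are continuous first,
then discrete, both zero-based.

NEXUS export writes the discrete block as a standard-datatype matrix with
``{01}``-style polymorphism and an ASSUMPTIONS typeset for ordering; it
is readable by dendropy and mainstream NEXUS software.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .characters import CharacterMatrix, CharacterError, format_state_set, parse_state_set

__all__ = ["write_tnt", "read_tnt", "write_nexus_discrete"]


def _sanitize(label: str) -> str:
    return re.sub(r"\s+", "_", label.strip())


def _cont_cell(mean, lo, hi) -> str:
    if not np.isfinite(mean):
        return "?"
    if np.isclose(lo, hi):
        return f"{mean:.6f}"
    return f"{lo:.6f}-{hi:.6f}"


def _disc_cell(cell) -> str:
    if cell is None:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return "[" + "".join(str(s) for s in sorted(cell)) + "]"


def write_tnt(matrix: CharacterMatrix, path) -> None:
    n_cont = len(matrix.continuous_names)
    n_disc = len(matrix.discrete_names)
    lines = [
        "xread",
        "'combined continuous + discrete placement matrix'",
        f"{n_cont + n_disc} {len(matrix.species)}",
    ]
    if n_cont:
        lines.append("&[cont]")
        for sp in matrix.species:
            cells = [
                _cont_cell(
                    matrix.cont_mean.at[sp, ch],
                    matrix.cont_lo.at[sp, ch],
                    matrix.cont_hi.at[sp, ch],
                )
                for ch in matrix.continuous_names
            ]
            lines.append(f"{_sanitize(sp)} " + " ".join(cells))
    if n_disc:
        lines.append("&[num]")
        for sp in matrix.species:
            cells = "".join(_disc_cell(matrix.disc.at[sp, ch]) for ch in matrix.discrete_names)
            lines.append(f"{_sanitize(sp)} {cells}")
    lines.append(";")
    ordered_idx = [
        n_cont + j
        for j, ch in enumerate(matrix.discrete_names)
        if bool(matrix.ordered.get(ch, False))
    ]
    if ordered_idx:
        lines.append("ccode + " + " ".join(str(i) for i in ordered_idx) + ";")
    lines.append("proc /;")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_RANGE = re.compile(r"^(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)-(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)$")


def _parse_cont_cell(token: str):
    if token == "?":
        return np.nan, np.nan, np.nan
    m = _RANGE.match(token)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return (lo + hi) / 2.0, lo, hi
    v = float(token)
    return v, v, v


def _parse_disc_row(text: str):
    cells = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "[":
            j = text.index("]", i)
            cells.append(frozenset(int(s) for s in text[i + 1 : j]))
            i = j + 1
        elif c in "?-":
            cells.append(None)
            i += 1
        else:
            cells.append(frozenset((int(c),)))
            i += 1
    return cells


def read_tnt(path, queries=()) -> CharacterMatrix:
    with open(path) as fh:
        text = fh.read()
    body = re.search(r"xread(.*?);", text, flags=re.S)
    if body is None:
        raise CharacterError("no xread block found")
    lines = [l.strip() for l in body.group(1).splitlines() if l.strip()]
    lines = [l for l in lines if not l.startswith("'")]
    header = lines.pop(0).split()
    n_char, n_tax = int(header[0]), int(header[1])
    section = None
    cont_rows: dict[str, list] = {}
    disc_rows: dict[str, list] = {}
    for line in lines:
        if line.startswith("&"):
            section = "cont" if "cont" in line else "num"
            continue
        name, _, rest = line.partition(" ")
        if section == "cont":
            cont_rows[name] = [_parse_cont_cell(tok) for tok in rest.split()]
        elif section == "num":
            disc_rows[name] = _parse_disc_row(rest.strip())
        else:
            raise CharacterError(f"matrix row outside a &[...] section: {line!r}")
    species = list(cont_rows or disc_rows)
    n_cont = len(next(iter(cont_rows.values()))) if cont_rows else 0
    n_disc = len(next(iter(disc_rows.values()))) if disc_rows else 0
    if n_cont + n_disc != n_char or len(species) != n_tax:
        raise CharacterError("xread dimensions do not match the matrix body")
    cont_names = [f"cont{j+1}" for j in range(n_cont)]
    disc_names = [f"disc{j+1}" for j in range(n_disc)]
    mean = pd.DataFrame(
        [[cell[0] for cell in cont_rows.get(sp, [])] for sp in species]
        if n_cont else np.empty((len(species), 0)),
        index=species, columns=cont_names,
    )
    lo = pd.DataFrame(
        [[cell[1] for cell in cont_rows.get(sp, [])] for sp in species]
        if n_cont else np.empty((len(species), 0)),
        index=species, columns=cont_names,
    )
    hi = pd.DataFrame(
        [[cell[2] for cell in cont_rows.get(sp, [])] for sp in species]
        if n_cont else np.empty((len(species), 0)),
        index=species, columns=cont_names,
    )
    # TNT files carry no specimen counts: range cells imply n > 1
    n_df = pd.DataFrame(1, index=species, columns=cont_names, dtype=int)
    if n_cont:
        n_df = n_df.where(~(hi > lo), 2)
    disc = pd.DataFrame(
        {name: [disc_rows[sp][j] for sp in species] for j, name in enumerate(disc_names)},
        index=species, dtype=object,
    ) if n_disc else pd.DataFrame(index=species)
    ordered = pd.Series(False, index=disc_names, dtype=bool)
    ccode = re.search(r"ccode\s*\+([^;]*);", text)
    if ccode:
        for idx in (int(tok) for tok in ccode.group(1).split()):
            if idx >= n_cont:
                ordered.iloc[idx - n_cont] = True
    return CharacterMatrix(
        cont_mean=mean, cont_lo=lo, cont_hi=hi, cont_n=n_df,
        disc=disc, ordered=ordered, queries=frozenset(queries),
    )


def write_nexus_discrete(matrix: CharacterMatrix, path) -> None:
    """NEXUS standard-datatype export of the discrete partition."""
    chars = matrix.discrete_names
    if not chars:
        raise CharacterError("matrix has no discrete characters")
    max_state = 0
    for ch in chars:
        for cell in matrix.disc[ch]:
            if cell:
                max_state = max(max_state, max(cell))
    symbols = "".join(str(s) for s in range(max_state + 1))
    rows = []
    for sp in matrix.species:
        cells = []
        for ch in chars:
            cell = matrix.disc.at[sp, ch]
            if cell is None:
                cells.append("?")
            elif len(cell) == 1:
                cells.append(str(next(iter(cell))))
            else:
                cells.append("{" + "".join(str(s) for s in sorted(cell)) + "}")
        rows.append(f"    {_sanitize(sp)}  " + "".join(cells))
    ordered_idx = [
        str(j + 1) for j, ch in enumerate(chars) if bool(matrix.ordered.get(ch, False))
    ]
    unordered_idx = [
        str(j + 1) for j, ch in enumerate(chars) if not bool(matrix.ordered.get(ch, False))
    ]
    blocks = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(matrix.species)} NCHAR={len(chars)};",
        f'  FORMAT DATATYPE=STANDARD GAP=- MISSING=? SYMBOLS="{symbols}";',
        "  MATRIX",
        *rows,
        "  ;",
        "END;",
    ]
    typeset_parts = []
    if ordered_idx:
        typeset_parts.append("ord: " + " ".join(ordered_idx))
    if unordered_idx:
        typeset_parts.append("unord: " + " ".join(unordered_idx))
    if typeset_parts:
        blocks += [
            "BEGIN ASSUMPTIONS;",
            "  TYPESET * default = " + ", ".join(typeset_parts) + ";",
            "END;",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(blocks) + "\n")
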