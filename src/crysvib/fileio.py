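"""Structure and trajectory file I/O: CIF, VASP POSCAR, extended XYZ.

CIF files are parsed with :mod:`gemmi`'s CIF reader (cell parameters plus
the ``_atom_site`` loop; structures are treated as P1 — symmetry expansion
is out of scope).  POSCAR and extended-XYZ (``Lattice="..."`` comment
records, optional per-frame ``dipole="Mx My Mz"``) use small dedicated
readers, since those formats are line-oriented and trivially specified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from gemmi import cif as gcif

from .elements import KNOWN_ELEMENTS
from .errors import ElementError, FormatError
from .structures import Crystal, lattice_from_parameters, lattice_parameters

__all__ = [
    "read_structure",
    "write_structure",
    "read_xyz_frames",
    "write_xyz_frames",
    "Frame",
]


@dataclass
class Frame:
    """One trajectory frame: symbols, Cartesian positions (Å), cell, extras."""

    symbols: list
    positions: np.ndarray
    lattice: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def as_crystal(self, molecules=None) -> Crystal:
        if self.lattice is None:
            raise FormatError("frame has no lattice record")
        frac = self.positions @ np.linalg.inv(self.lattice)
        return Crystal(self.lattice, self.symbols, frac, molecules=molecules)


# --------------------------------------------------------------------------
# dispatch

_DIALECTS = ("cif", "poscar", "xyz")


def _guess_dialect(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "cif":
        return "cif"
    if suffix in ("xyz", "extxyz"):
        return "xyz"
    if suffix in ("vasp", "poscar") or path.name.upper().startswith(("POSCAR", "CONTCAR")):
        return "poscar"
    raise FormatError(f"cannot guess structure dialect for {path.name!r}")


def read_structure(path, dialect: str | None = None) -> Crystal:
    """Read a crystal structure from CIF, POSCAR or (single-frame) XYZ."""
    path = Path(path)
    if dialect is None:
        dialect = _guess_dialect(path)
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "cif":
        return _read_cif(path)
    if dialect == "poscar":
        return _read_poscar(path)
    frames = read_xyz_frames(path)
    if not frames:
        raise FormatError(f"{path.name}: no frames")
    return frames[0].as_crystal()


def write_structure(crystal: Crystal, path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = _guess_dialect(path)
    if dialect == "cif":
        _write_cif(crystal, path)
    elif dialect == "poscar":
        _write_poscar(crystal, path)
    elif dialect == "xyz":
        frame = Frame(crystal.symbols, crystal.cart_coords(), crystal.lattice)
        write_xyz_frames([frame], path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# CIF

_CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)


def _cif_number(text: str) -> float:
    # strip s.u. parentheses: "5.421(3)" → 5.421
    return float(re.sub(r"\(.*\)", "", text))


def _read_cif(path: Path) -> Crystal:
    try:
        doc = gcif.read_file(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise FormatError(f"{path.name}: {exc}") from exc
    block = doc.sole_block() if len(doc) == 1 else doc[0]
    try:
        params = [_cif_number(block.find_value(tag)) for tag in _CELL_TAGS]
    except TypeError:
        raise FormatError(f"{path.name}: missing cell parameters") from None
    lattice = lattice_from_parameters(*params)

    sym_col = None
    for tag in ("_atom_site_type_symbol", "_atom_site_label"):
        table = block.find([tag, "_atom_site_fract_x", "_atom_site_fract_y",
                            "_atom_site_fract_z"])
        if len(table) > 0:
            sym_col = tag
            break
    if sym_col is None:
        raise FormatError(f"{path.name}: no _atom_site loop with fractional coords")

    symbols, fracs = [], []
    for row in table:
        raw = row[0]
        sym = re.match(r"[A-Za-z]{1,2}", raw)
        if not sym:
            raise FormatError(f"{path.name}: bad atom symbol {raw!r}")
        symbol = sym.group(0).capitalize()
        if symbol not in KNOWN_ELEMENTS:
            # labels like "Ca1" may really be C; prefer single-letter fallback
            if symbol[0] in KNOWN_ELEMENTS:
                symbol = symbol[0]
            else:
                raise ElementError(f"{path.name}: unknown element {raw!r}")
        symbols.append(symbol)
        fracs.append([_cif_number(row[i]) for i in (1, 2, 3)])
    return Crystal(lattice, symbols, np.array(fracs), provenance=f"cif:{path.name}")


def _write_cif(crystal: Crystal, path: Path) -> None:
    a, b, c, al, be, ga = lattice_parameters(crystal.lattice)
    lines = [
        "data_crysvib",
        "_symmetry_space_group_name_H-M   'P 1'",
        f"_cell_length_a     {a:.8f}",
        f"_cell_length_b     {b:.8f}",
        f"_cell_length_c     {c:.8f}",
        f"_cell_angle_alpha  {al:.8f}",
        f"_cell_angle_beta   {be:.8f}",
        f"_cell_angle_gamma  {ga:.8f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    counts: dict[str, int] = {}
    for sym, fr in zip(crystal.symbols, crystal.frac_coords):
        counts[sym] = counts.get(sym, 0) + 1
        lines.append(
            f"{sym}{counts[sym]} {sym} {fr[0]:.10f} {fr[1]:.10f} {fr[2]:.10f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# POSCAR

def _read_poscar(path: Path) -> Crystal:
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines()]
    try:
        scale = float(lines[1])
        lattice = scale * np.array(
            [[float(x) for x in lines[i].split()[:3]] for i in (2, 3, 4)]
        )
        species = lines[5].split()
        counts = [int(x) for x in lines[6].split()]
        mode_line = 7
        if lines[mode_line].strip().lower().startswith("s"):  # selective dynamics
            mode_line += 1
        direct = lines[mode_line].strip().lower().startswith(("d", "f"))
        coords = []
        for i in range(sum(counts)):
            coords.append([float(x) for x in lines[mode_line + 1 + i].split()[:3]])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path.name}: malformed POSCAR ({exc})") from exc
    symbols = [s for s, n in zip(species, counts) for _ in range(n)]
    for s in symbols:
        if s not in KNOWN_ELEMENTS:
            raise ElementError(f"{path.name}: unknown element {s!r}")
    coords = np.array(coords)
    frac = coords if direct else coords @ np.linalg.inv(lattice)
    return Crystal(lattice, symbols, frac, provenance=f"poscar:{path.name}")


def _write_poscar(crystal: Crystal, path: Path) -> None:
    order: list[str] = []
    for s in crystal.symbols:
        if s not in order:
            order.append(s)
    lines = ["crysvib structure", "1.0"]
    for v in crystal.lattice:
        lines.append(f"  {v[0]:20.12f} {v[1]:20.12f} {v[2]:20.12f}")
    lines.append("  " + "  ".join(order))
    lines.append(
        "  " + "  ".join(str(sum(1 for s in crystal.symbols if s == o)) for o in order)
    )
    lines.append("Direct")
    for o in order:
        for s, fr in zip(crystal.symbols, crystal.frac_coords):
            if s == o:
                lines.append(f"  {fr[0]:18.12f} {fr[1]:18.12f} {fr[2]:18.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# extended XYZ

_KV_RE = re.compile(r'(\w+)=("([^"]*)"|(\S+))')


def _parse_extxyz_comment(comment: str) -> dict:
    info = {}
    for m in _KV_RE.finditer(comment):
        key = m.group(1)
        val = m.group(3) if m.group(3) is not None else m.group(4)
        info[key] = val
    return info


def read_xyz_frames(path) -> list[Frame]:
    """Read an (extended) XYZ trajectory.

    The comment line may carry ``Lattice="ax ay az bx by bz cx cy cz"``
    (row-major lattice vectors) and arbitrary ``key=value`` pairs; a
    ``dipole="Mx My Mz"`` record (e·Å) is exposed as a float array in
    ``frame.info["dipole"]``.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            nat = int(text[i].strip())
        except ValueError:
            raise FormatError(f"{path.name}: expected atom count at line {i + 1}")
        if i + 1 + nat > len(text):
            raise FormatError(f"{path.name}: truncated frame at line {i + 1}")
        info = _parse_extxyz_comment(text[i + 1])
        lattice = None
        if "Lattice" in info:
            vals = [float(x) for x in info.pop("Lattice").split()]
            if len(vals) != 9:
                raise FormatError(f"{path.name}: Lattice needs 9 numbers")
            lattice = np.array(vals).reshape(3, 3)
        if "dipole" in info:
            info["dipole"] = np.array([float(x) for x in info["dipole"].split()])
        if "time_fs" in info:
            info["time_fs"] = float(info["time_fs"])
        symbols, pos = [], []
        for ln in text[i + 2 : i + 2 + nat]:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path.name}: bad atom line {ln!r}")
            symbols.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        frames.append(Frame(symbols, np.array(pos), lattice, info))
        i += 2 + nat
    return frames


def write_xyz_frames(frames, path) -> None:
    out = []
    for fr in frames:
        out.append(str(len(fr.symbols)))
        comment = []
        if fr.lattice is not None:
            flat = " ".join(f"{x:.10f}" for x in np.asarray(fr.lattice).ravel())
            comment.append(f'Lattice="{flat}"')
        for k, v in fr.info.items():
            if isinstance(v, np.ndarray):
                comment.append(f'{k}="' + " ".join(f"{x:.10g}" for x in v) + '"')
            else:
                comment.append(f"{k}={v}")
        comment.append('Properties=species:S:1:pos:R:3')
        out.append(" ".join(comment))
        for s, p in zip(fr.symbols, fr.positions):
            out.append(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}")
    Path(path).write_text("\n".join(out) + "\n")
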