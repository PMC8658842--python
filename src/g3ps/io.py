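"""Pharmacophore file I/O: native JSON and a plain-text ``.phar`` dialect.

JSON is the lossless native format. The phar dialect is a line-oriented
text format with fixed 4-decimal coordinates (so round-trips agree to
1e-4 angstrom):

    NAME <free text>                      optional, once per record
    CODE x y z tolerance hasDir nx ny nz  one feature per line
    EXCL x y z radius                     one exclusion sphere per line
    ATOM x y z                            one molecule atom per line
    $$$$                                  record terminator

``hasDir`` is 0 or 1; the three direction components are written as 0
when absent. Feature codes are free strings by default; pass
``strict_codes=True`` to reject codes outside the built-in alphabet.
Multiple records concatenated in one file form a library.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ParseError
from .model import (
    EXCLUSION_CODE,
    FEATURE_CODES,
    ExclusionSphere,
    Feature,
    Pharmacophore,
)

__all__ = [
    "read_pharmacophore",
    "write_pharmacophore",
    "read_library",
    "write_library",
    "pharmacophore_to_dict",
    "pharmacophore_from_dict",
]


def pharmacophore_to_dict(p: Pharmacophore) -> dict:
    d: dict = {"name": p.name, "features": [], "exclusions": []}
    for f in p.features:
        fd = {
            "type": f.type,
            "position": [float(x) for x in f.position],
            "tolerance": float(f.tolerance),
        }
        if f.direction is not None:
            fd["direction"] = [float(x) for x in f.direction]
        if f.optional:
            fd["optional"] = True
        d["features"].append(fd)
    for s in p.exclusions:
        d["exclusions"].append(
            {"center": [float(x) for x in s.center], "radius": float(s.radius)}
        )
    if p.atoms is not None:
        d["atoms"] = [[float(x) for x in row] for row in p.atoms]
    return d


def pharmacophore_from_dict(d: dict, strict_codes: bool = False) -> Pharmacophore:
    feats = []
    for fd in d.get("features", []):
        code = str(fd["type"])
        _check_code(code, strict_codes, None)
        feats.append(
            Feature(
                type=code,
                position=fd["position"],
                tolerance=fd["tolerance"],
                direction=fd.get("direction"),
                optional=bool(fd.get("optional", False)),
            )
        )
    excl = [
        ExclusionSphere(e["center"], e["radius"]) for e in d.get("exclusions", [])
    ]
    atoms = d.get("atoms")
    return Pharmacophore(
        name=str(d.get("name", "")),
        features=feats,
        exclusions=excl,
        atoms=np.asarray(atoms, dtype=float) if atoms else None,
    )


def _check_code(code: str, strict: bool, line: int | None):
    if strict and code not in FEATURE_CODES:
        raise ParseError(f"unknown feature code {code!r}", line)


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _phar_record_lines(p: Pharmacophore) -> Iterator[str]:
    if p.name:
        yield f"NAME {p.name}"
    for f in p.features:
        has_dir = f.direction is not None
        d = f.direction if has_dir else np.zeros(3)
        yield " ".join(
            [f.type]
            + [_fmt(v) for v in f.position]
            + [_fmt(f.tolerance), str(int(has_dir))]
            + [_fmt(v) for v in d]
        )
    for s in p.exclusions:
        yield " ".join(["EXCL"] + [_fmt(v) for v in s.center] + [_fmt(s.radius)])
    if p.atoms is not None:
        for a in p.atoms:
            yield " ".join(["ATOM"] + [_fmt(v) for v in a])
    yield "$$$$"


def _parse_floats(tokens: list[str], n: int, line: int) -> list[float]:
    if len(tokens) != n:
        raise ParseError(f"expected {n} numeric fields, got {len(tokens)}", line)
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise ParseError(f"non-numeric field: {exc}", line) from None


def iter_phar_records(
    text: str, strict_codes: bool = False
) -> Iterator[Pharmacophore]:
    """Parse concatenated phar records from a text blob."""
    name = ""
    feats: list[Feature] = []
    excl: list[ExclusionSphere] = []
    atoms: list[list[float]] = []
    seen_any = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "$$$$":
            yield Pharmacophore(
                name=name,
                features=feats,
                exclusions=excl,
                atoms=np.asarray(atoms) if atoms else None,
            )
            name, feats, excl, atoms = "", [], [], []
            seen_any = False
            continue
        seen_any = True
        tokens = line.split()
        tag = tokens[0]
        if tag == "NAME":
            name = line[len("NAME") :].strip()
        elif tag == "EXCL" or tag == EXCLUSION_CODE:
            vals = _parse_floats(tokens[1:], 4, lineno)
            excl.append(ExclusionSphere(vals[:3], vals[3]))
        elif tag == "ATOM":
            atoms.append(_parse_floats(tokens[1:], 3, lineno))
        else:
            _check_code(tag, strict_codes, lineno)
            vals = _parse_floats(tokens[1:], 8, lineno)
            has_dir = int(vals[4]) != 0
            feats.append(
                Feature(
                    type=tag,
                    position=vals[:3],
                    tolerance=vals[3],
                    direction=vals[5:8] if has_dir else None,
                )
            )
    if seen_any:
        # final record without terminator is accepted
        yield Pharmacophore(
            name=name,
            features=feats,
            exclusions=excl,
            atoms=np.asarray(atoms) if atoms else None,
        )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".json", ".jsonl"):
        return "json"
    return "phar"


def read_pharmacophore(
    path, format: str | None = None, strict_codes: bool = False
) -> Pharmacophore:
    """Read one pharmacophore from ``path`` (format inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        try:
            return pharmacophore_from_dict(json.loads(text), strict_codes)
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ParseError(f"bad JSON pharmacophore in {path}: {exc}") from None
    if fmt == "phar":
        records = list(iter_phar_records(text, strict_codes))
        if not records:
            return Pharmacophore()
        return records[0]
    raise ValueError(f"unknown format {fmt!r}")


def write_pharmacophore(p: Pharmacophore, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(pharmacophore_to_dict(p), indent=2) + "\n")
    elif fmt == "phar":
        path.write_text("\n".join(_phar_record_lines(p)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_library(
    path, format: str | None = None, strict_codes: bool = False
) -> list[Pharmacophore]:
    """Read a library: concatenated phar records or a JSON-lines file."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        out = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append(pharmacophore_from_dict(json.loads(line), strict_codes))
            except (KeyError, TypeError, json.JSONDecodeError) as exc:
                raise ParseError(f"bad JSON record: {exc}", lineno) from None
        return out
    return list(iter_phar_records(text, strict_codes))


def write_library(
    entries: Iterable[Pharmacophore], path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        lines = [json.dumps(pharmacophore_to_dict(p)) for p in entries]
    else:
        lines = ["\n".join(_phar_record_lines(p)) for p in entries]
    path.write_text("\n".join(lines) + "\n")
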