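"""Landmark tables, modularity hypotheses, and their file formats.

Two round-trippable dialects are supported for 3D landmark configurations:

``csv-long``
    One row per specimen x landmark with header
    ``specimen_id,species_id,group,landmark,x,y,z``; a missing landmark has
    empty coordinate cells.

``tps3``
    A 3D analogue of the classical landmark format: ``LM3=<p>`` followed by
    ``p`` lines of three whitespace-separated reals and an ``ID=<specimen>``
    footer per specimen; missing landmarks are written as three ``NaN``
    tokens.  The dialect carries no species/group metadata; on read,
    ``species_id`` defaults to the specimen id and ``group`` is empty.

Module maps (which landmark belongs to which named module under each
hypothesis) are read from a YAML config; landmark labels are 1-based integers
rendered as text, and ranges like ``"1-10"`` are accepted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import yaml

from .trees import Tree

__all__ = [
    "LandmarkTable",
    "ModuleHypothesis",
    "read_landmarks",
    "write_landmarks",
    "read_tree",
    "read_module_map",
]


class FormatError(ValueError):
    """Input file does not conform to the declared dialect."""


@dataclass
class LandmarkTable:
    """n specimens x p landmarks x 3 coordinates with labels and a missingness mask.

    ``coords`` holds NaN wherever ``missing_mask`` is True; everywhere else
    coordinates must be finite.  All specimens share one ordered landmark
    label list.
    """

    specimen_ids: list[str]
    species_ids: list[str]
    groups: list[str]
    landmark_labels: list[str]
    coords: np.ndarray  # (n, p, 3)
    missing_mask: np.ndarray  # (n, p) bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    def validate(self):
        n, p = len(self.specimen_ids), len(self.landmark_labels)
        if p < 4:
            raise ValueError(f"need at least 4 landmarks, got {p}")
        if len(set(self.specimen_ids)) != n:
            dupes = {s for s in self.specimen_ids if self.specimen_ids.count(s) > 1}
            raise ValueError(f"duplicate specimen ids: {sorted(dupes)}")
        if len(self.species_ids) != n or len(self.groups) != n:
            raise ValueError("species/group label lists must match specimen count")
        if self.coords.shape != (n, p, 3):
            raise ValueError(f"coords shape {self.coords.shape} != {(n, p, 3)}")
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape mismatch")
        present = ~self.missing_mask
        if not np.all(np.isfinite(self.coords[present])):
            bad = [self.specimen_ids[i] for i in
                   np.unique(np.argwhere(~np.isfinite(self.coords).all(axis=2) & present)[:, 0])]
            raise ValueError(f"non-finite coordinates outside missing mask in {bad}")

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_labels)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def subset(self, specimen_ids: list[str]) -> "LandmarkTable":
        idx = {s: i for i, s in enumerate(self.specimen_ids)}
        missing = [s for s in specimen_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown specimens: {missing}")
        rows = [idx[s] for s in specimen_ids]
        return LandmarkTable(
            [self.specimen_ids[i] for i in rows],
            [self.species_ids[i] for i in rows],
            [self.groups[i] for i in rows],
            list(self.landmark_labels),
            self.coords[rows].copy(),
            self.missing_mask[rows].copy(),
        )

    def by_group(self, group: str) -> "LandmarkTable":
        rows = [s for s, g in zip(self.specimen_ids, self.groups) if g == group]
        if not rows:
            raise KeyError(f"no specimens in group {group!r}")
        return self.subset(rows)

    def complete_specimens(self) -> list[str]:
        return [s for s, m in zip(self.specimen_ids, self.missing_mask) if not m.any()]


@dataclass
class ModuleHypothesis:
    """A named partition of the landmark set into >= 2 modules."""

    name: str
    assignment: dict[str, str]  # landmark label -> module name
    module_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        mods = list(dict.fromkeys(self.assignment.values()))
        if not self.module_names:
            self.module_names = mods
        if set(self.module_names) != set(mods):
            raise ValueError("module_names inconsistent with assignment")
        if len(self.module_names) < 2:
            raise ValueError(f"hypothesis {self.name!r} needs >= 2 modules")

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def members(self, module: str) -> list[str]:
        return [lm for lm, m in self.assignment.items() if m == module]

    def validate_against(self, landmark_labels: list[str]):
        """Check the hypothesis exactly partitions the given landmark set."""
        labels = set(landmark_labels)
        assigned = set(self.assignment)
        unassigned = sorted(labels - assigned, key=_label_key)
        if unassigned:
            raise ValueError(
                f"hypothesis {self.name!r}: landmark {unassigned[0]} unassigned"
                + (f" (and {len(unassigned) - 1} more)" if len(unassigned) > 1 else "")
            )
        extra = sorted(assigned - labels, key=_label_key)
        if extra:
            raise ValueError(f"hypothesis {self.name!r}: unknown landmarks {extra}")
        for m in self.module_names:
            if not self.members(m):
                raise ValueError(f"hypothesis {self.name!r}: module {m!r} is empty")

    def indices(self, landmark_labels: list[str]) -> dict[str, np.ndarray]:
        """Module name -> integer landmark indices into ``landmark_labels``."""
        self.validate_against(landmark_labels)
        pos = {lab: i for i, lab in enumerate(landmark_labels)}
        return {
            m: np.array(sorted(pos[lm] for lm in self.members(m)), dtype=int)
            for m in self.module_names
        }


def _label_key(label: str):
    return (0, int(label)) if str(label).isdigit() else (1, str(label))


# ---------------------------------------------------------------------------
# landmark file I/O


def read_landmarks(path, format: str = "csv-long") -> LandmarkTable:
    if format == "csv-long":
        return _read_csv_long(path)
    if format == "tps3":
        return _read_tps3(path)
    raise ValueError(f"unknown landmark format {format!r}")


def write_landmarks(table: LandmarkTable, path, format: str = "csv-long") -> None:
    table.validate()
    if format == "csv-long":
        _write_csv_long(table, path)
    elif format == "tps3":
        _write_tps3(table, path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def _read_csv_long(path) -> LandmarkTable:
    per_spec: dict[str, dict] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"specimen_id", "species_id", "group", "landmark", "x", "y", "z"}
        if reader.fieldnames is None or not need.issubset(reader.fieldnames):
            raise FormatError(f"csv-long header must contain {sorted(need)}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["specimen_id"]
            if sid not in per_spec:
                per_spec[sid] = {"species": row["species_id"], "group": row["group"],
                                 "landmarks": [], "coords": [], "mask": []}
                order.append(sid)
            rec = per_spec[sid]
            rec["landmarks"].append(row["landmark"])
            cells = (row["x"], row["y"], row["z"])
            if all(c.strip() == "" for c in cells):
                rec["coords"].append((np.nan,) * 3)
                rec["mask"].append(True)
            else:
                try:
                    rec["coords"].append(tuple(float(c) for c in cells))
                except ValueError:
                    raise FormatError(f"line {lineno}: non-numeric coordinate {cells}")
                rec["mask"].append(False)
    if not order:
        raise FormatError("empty csv-long file")
    labels = per_spec[order[0]]["landmarks"]
    for sid in order:
        if per_spec[sid]["landmarks"] != labels:
            raise FormatError(
                f"specimen {sid!r} has landmarks {per_spec[sid]['landmarks']}"
                f" inconsistent with {labels}"
            )
    return LandmarkTable(
        order,
        [per_spec[s]["species"] for s in order],
        [per_spec[s]["group"] for s in order],
        labels,
        np.array([per_spec[s]["coords"] for s in order]),
        np.array([per_spec[s]["mask"] for s in order]),
    )


def _write_csv_long(table: LandmarkTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "species_id", "group", "landmark", "x", "y", "z"])
        for i, sid in enumerate(table.specimen_ids):
            for j, lm in enumerate(table.landmark_labels):
                if table.missing_mask[i, j]:
                    w.writerow([sid, table.species_ids[i], table.groups[i], lm, "", "", ""])
                else:
                    w.writerow(
                        [sid, table.species_ids[i], table.groups[i], lm]
                        + [repr(float(v)) for v in table.coords[i, j]]
                    )


def _read_tps3(path) -> LandmarkTable:
    specs: list[tuple[str, list, list]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    i, n_lines = 0, len(lines)
    while i < n_lines:
        if not lines[i]:
            i += 1
            continue
        if not lines[i].upper().startswith("LM3="):
            raise FormatError(f"line {i + 1}: expected LM3= record, got {lines[i]!r}")
        try:
            p = int(lines[i].split("=", 1)[1])
        except ValueError:
            raise FormatError(f"line {i + 1}: bad landmark count in {lines[i]!r}")
        coords, mask = [], []
        i += 1
        for k in range(p):
            if i >= n_lines:
                raise FormatError(f"unexpected end of file inside coordinate block")
            toks = lines[i].split()
            if len(toks) != 3:
                raise FormatError(f"line {i + 1}: expected 3 coordinates, got {lines[i]!r}")
            try:
                xyz = [float(t) for t in toks]
            except ValueError:
                raise FormatError(f"line {i + 1}: non-numeric coordinate in {lines[i]!r}")
            miss = any(np.isnan(v) for v in xyz)
            coords.append([np.nan] * 3 if miss else xyz)
            mask.append(miss)
            i += 1
        if i >= n_lines or not lines[i].upper().startswith("ID="):
            raise FormatError(f"line {i + 1}: expected ID= footer")
        sid = lines[i].split("=", 1)[1]
        specs.append((sid, coords, mask))
        i += 1
    if not specs:
        raise FormatError("empty tps3 file")
    p = len(specs[0][1])
    for sid, coords, _ in specs:
        if len(coords) != p:
            raise FormatError(f"specimen {sid!r} has {len(coords)} landmarks, expected {p}")
    labels = [str(k + 1) for k in range(p)]
    return LandmarkTable(
        [s[0] for s in specs],
        [s[0] for s in specs],
        [""] * len(specs),
        labels,
        np.array([s[1] for s in specs]),
        np.array([s[2] for s in specs]),
    )


def _write_tps3(table: LandmarkTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, sid in enumerate(table.specimen_ids):
            fh.write(f"LM3={table.n_landmarks}\n")
            for j in range(table.n_landmarks):
                if table.missing_mask[i, j]:
                    fh.write("NaN NaN NaN\n")
                else:
                    fh.write(" ".join(repr(float(v)) for v in table.coords[i, j]) + "\n")
            fh.write(f"ID={sid}\n")


# ---------------------------------------------------------------------------
# trees and module maps


def read_tree(path, prune_to: list[str] | None = None) -> Tree:
    """Read a rooted Newick tree, optionally pruning it to a tip set."""
    tree = Tree.from_file(path)
    if prune_to is not None:
        tree = tree.prune(prune_to)
    tree.check_ultrametric()
    return tree


def _expand_landmark_spec(spec) -> list[str]:
    out: list[str] = []
    items = spec if isinstance(spec, (list, tuple)) else [spec]
    for item in items:
        s = str(item).strip()
        if "-" in s and not s.lstrip("-").isdigit():
            a, b = s.split("-", 1)
            out.extend(str(k) for k in range(int(a), int(b) + 1))
        else:
            out.append(s)
    return out


def read_module_map(path) -> list[ModuleHypothesis]:
    """Read modularity hypotheses from a YAML config.

    Layout::

        hypotheses:
          H2:
            attraction: ["33-37"]
            reproduction: ["1-32"]
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "hypotheses" not in cfg:
        raise FormatError("module map must contain a top-level 'hypotheses' mapping")
    out = []
    for name, modules in cfg["hypotheses"].items():
        assignment: dict[str, str] = {}
        for module, spec in modules.items():
            for lm in _expand_landmark_spec(spec):
                if lm in assignment:
                    raise ValueError(
                        f"hypothesis {name!r}: landmark {lm} assigned to both "
                        f"{assignment[lm]!r} and {module!r}"
                    )
                assignment[lm] = str(module)
        out.append(ModuleHypothesis(str(name), assignment, [str(m) for m in modules]))
    return out
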