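"""Batch regime census over enumerated graphs, with checkpointed output.

The census classifies every connected graph of the requested orders and
writes one tab-separated record per isomorphism class, in ascending
canonical-id order.  Runs are resumable: completed leading records of an
existing output file are kept and classification continues after them, so an
interrupted run loses at most one graph.  Output is byte-identical across
resumes because processing order is deterministic.

Exact classification is the authority for orders <= 7 (every non-regular
graph gets a certified rational fixation function); the numeric scan is the
pragmatic mode for order 8, where exact confirmation is applied to every
graph whose scan shows a transition or a near-tie.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Literal, Sequence, TextIO

from .graph import UndirectedGraph
from .enumeration import enumerate_connected
from .regimes import (EXTENDED_GRID, STANDARD_GRID, RegimeProfile,
                      classify)

__all__ = [
    "CensusRecord", "CensusSummary", "run_census", "summarize",
    "read_census", "read_config", "barcode_export", "TABLE_COLUMNS",
]

TABLE_COLUMNS = ("id", "graph6", "order", "size", "method", "classification",
                 "pattern", "transitions", "inconclusive")

logger = logging.getLogger(__name__)


def read_config(path: str | os.PathLike) -> dict:
    """Parse a ``key = value`` census configuration file.

    Recognised keys: ``grid`` and ``extended_grid`` (``lo:hi:step``),
    ``method``, ``out`` (checkpoint path), ``workers``.  Blank lines and
    ``#`` comments are ignored; CLI flags override config values.
    """
    out: dict = {}
    for line in open(path, encoding="utf-8"):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in ("grid", "extended_grid"):
            lo, hi, step = (float(x) for x in value.split(":"))
            pts = []
            x = lo
            while x <= hi + 1e-12:
                pts.append(round(x, 10))
                x += step
            out[key] = tuple(pts)
        elif key == "workers":
            out[key] = int(value)
        elif key in ("method", "out"):
            out[key] = value
        else:
            raise ValueError(f"unknown census config key {key!r}")
    return out


@dataclass(frozen=True)
class CensusRecord:
    """One classified isomorphism class."""

    id: int
    graph6: str
    order: int
    size: int
    profile: RegimeProfile

    def to_row(self) -> str:
        trans = ";".join(
            f"{t.direction}@{t.r_c:.12g}"
            f"[{t.interval[0]},{t.interval[1]}]"
            for t in self.profile.transitions)
        return "\t".join([
            str(self.id), self.graph6, str(self.order), str(self.size),
            self.profile.method, self.profile.classification,
            self.profile.pattern, trans,
            "1" if self.profile.inconclusive else "0",
        ])

    @classmethod
    def from_row(cls, row: str) -> "CensusRecord":
        from .regimes import TransitionRecord
        parts = row.rstrip("\n").split("\t")
        gid, g6, order, size, method, classification, pattern, trans, inc = parts
        records = []
        if trans:
            for item in trans.split(";"):
                d, rest = item.split("@")
                rc, iv = rest.split("[")
                lo, hi = iv.rstrip("]").split(",")
                records.append(TransitionRecord(
                    interval=(Fraction(lo), Fraction(hi)), direction=d))
        profile = RegimeProfile(
            classification=classification,
            sequence=tuple(pattern.split("/")) if pattern else (),
            transitions=tuple(records), method=method,
            inconclusive=inc == "1")
        return cls(id=int(gid), graph6=g6, order=int(order), size=int(size),
                   profile=profile)


def run_census(orders: Sequence[int],
               method: Literal["exact", "numeric-scan"] = "exact",
               out: str | os.PathLike | None = None,
               resume: bool = False,
               grid: Sequence[float] = STANDARD_GRID,
               extended_grid: Sequence[float] = EXTENDED_GRID,
               confirm_exact: bool | None = None,
               workers: int = 1,
               progress: bool = False) -> Iterator[CensusRecord]:
    """Classify every connected graph of the given orders; yield records.

    With ``out`` set, records are appended to a TSV file (with header) as
    they complete — the checkpoint; ``resume=True`` skips records already
    present.  Records stream in ascending (order, canonical id).

    In numeric-scan mode, ``confirm_exact`` (default: on for orders <= 8)
    re-runs the exact classifier on every graph whose scan shows at least
    one transition or any inconclusive grid point, so transition counts are
    certified even when the bulk regime calls are only apparent.

    ``workers > 1`` classifies in a process pool; work is partitioned over
    the deterministic enumeration order and merged back in that order, so
    the output file is byte-identical for any worker count.
    """
    done: list[CensusRecord] = []
    if out is not None and resume and os.path.exists(out):
        done = read_census(out)
    fh: TextIO | None = None
    if out is not None:
        mode = "a" if done else "w"
        fh = open(out, mode, encoding="utf-8")
        if not done:
            fh.write("\t".join(TABLE_COLUMNS) + "\n")
    try:
        seen = 0
        todo: list[UndirectedGraph] = []
        for N in sorted(orders):
            for G in enumerate_connected(N):
                if seen < len(done):
                    # trust the checkpoint; ids are in deterministic order
                    rec = done[seen]
                    if rec.id != G.canonical_id:
                        raise RuntimeError(
                            "checkpoint does not match enumeration order; "
                            "remove the output file and restart")
                    seen += 1
                    yield rec
                    continue
                todo.append(G)

        args = [(G, method, tuple(grid), tuple(extended_grid),
                 confirm_exact if confirm_exact is not None else G.order <= 8)
                for G in todo]
        if workers > 1 and len(args) > 1:
            import multiprocessing as mp
            with mp.get_context("fork").Pool(workers) as pool:
                profiles = pool.imap(_classify_task, args, chunksize=8)
                yield from _emit(todo, profiles, fh, seen, progress)
        else:
            yield from _emit(todo, map(_classify_task, args), fh, seen,
                             progress)
    finally:
        if fh is not None:
            fh.close()


def _classify_task(arg) -> RegimeProfile:
    G, method, grid, extended_grid, confirm = arg
    logger.debug("classifying %s (order %d, %d edges)",
                 G.to_graph6(), G.order, G.size)
    profile = classify(G, method=method, grid=grid,
                       extended_grid=extended_grid)
    if (method == "numeric-scan" and confirm
            and (profile.transitions or profile.inconclusive)):
        profile = classify(G, method="exact")
    if profile.inconclusive:
        logger.warning("inconclusive classification for %s", G.to_graph6())
    return profile


def _emit(todo, profiles, fh, seen, progress):
    for G, profile in zip(todo, profiles):
        rec = CensusRecord(id=G.canonical_id, graph6=G.to_graph6(),
                           order=G.order, size=G.size, profile=profile)
        seen += 1
        if fh is not None:
            fh.write(rec.to_row() + "\n")
            fh.flush()
        if seen % 1000 == 0:
            logger.info("%d graphs classified", seen)
        if progress and seen % 100 == 0:
            import sys
            print(f"... {seen} graphs classified", file=sys.stderr)
        yield rec


def read_census(path: str | os.PathLike) -> list[CensusRecord]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    out = []
    for line in lines:
        if not line or line.startswith("id\t"):
            continue
        out.append(CensusRecord.from_row(line))
    return out


@dataclass
class CensusSummary:
    """Per-order counts in the taxonomy of the regime table:
    isothermal, global suppressor, global amplifier, and graphs with one or
    more transitions keyed by their direction pattern."""

    per_order: dict[int, dict] = field(default_factory=dict)

    def row(self, N: int) -> dict:
        return self.per_order[N]


def summarize(records: Iterable[CensusRecord]) -> CensusSummary:
    acc: dict[int, dict] = {}
    for rec in records:
        row = acc.setdefault(rec.order, {
            "total": 0, "isothermal": 0, "suppressor": 0, "amplifier": 0,
            "patterns": Counter(), "inconclusive": 0,
            "methods": set(),
        })
        row["total"] += 1
        row["methods"].add(rec.profile.method)
        if rec.profile.inconclusive:
            row["inconclusive"] += 1
        cls = rec.profile.classification
        if cls == "isothermal":
            row["isothermal"] += 1
        elif cls == "suppressor":
            row["suppressor"] += 1
        elif cls == "amplifier":
            row["amplifier"] += 1
        else:
            row["patterns"][rec.profile.pattern] += 1
    summary = CensusSummary(per_order=acc)
    for N, row in acc.items():
        counted = (row["isothermal"] + row["suppressor"] + row["amplifier"]
                   + sum(row["patterns"].values()))
        assert counted == row["total"], "summary counts must partition the total"
        row["exact"] = row["methods"] == {"exact"}
    return summary


def barcode_export(records: Iterable[CensusRecord],
                   grid: Sequence[float] = STANDARD_GRID,
                   sort: Literal["unsorted", "by-pattern"] = "unsorted",
                   out: str | os.PathLike | TextIO | None = None) -> list[list[int]]:
    """Sign matrix of D = Phi - Phi0 over the fitness grid: one row per
    graph, entries -1 (suppressor), 0 (tie/isothermal), +1 (amplifier).

    Exact records derive their signs from the certified transitions; scan
    records use their stored grid signs where available.  ``by-pattern``
    sorts rows lexicographically by sign pattern (the sorted barcode
    panels).
    """
    rows: list[tuple[list[int], int]] = []
    for rec in records:
        prof = rec.profile
        if prof.scan_signs is not None and prof.scan_grid is not None:
            lookup = dict(zip(prof.scan_grid, prof.scan_signs))
            signs = [lookup.get(float(r), 0) for r in grid]
        elif prof.classification == "isothermal":
            signs = [0 for _ in grid]
        else:
            # reconstruct from the certified transition structure
            seq = prof.sequence
            cuts = [t.r_c for t in prof.transitions]
            signs = []
            for r in grid:
                if r <= 1:
                    signs.append(0)
                    continue
                k = sum(1 for c in cuts if c < r)
                signs.append(1 if seq[k] == "A" else -1)
        rows.append((signs, rec.id))
    if sort == "by-pattern":
        rows.sort(key=lambda t: (t[0], t[1]))
    matrix = [signs for signs, _ in rows]
    if out is not None:
        close = False
        if not hasattr(out, "write"):
            out = open(out, "w", encoding="utf-8")
            close = True
        out.write("\t".join(f"{r:g}" for r in grid) + "\n")
        for signs in matrix:
            out.write("\t".join(str(s) for s in signs) + "\n")
        if close:
            out.close()
    return matrix
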