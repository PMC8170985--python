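"""Keyword-deck subset reader/writer and deck-to-problem conversion.

Supported keywords: *NODE, *ELEMENT_SOLID, *PART, *MAT_SIMPLIFIED_RUBBER/FOAM
(also accepted as *MAT_SIMPLIFIED_FOAM / *MAT_181), *DEFINE_CURVE,
*DEFINE_TABLE, *CONTROL_TIMESTEP, *CONTROL_TERMINATION.  Both the
comma-separated and the fixed-width card dialects are accepted; comment lines
start with ``$``.  Unknown keyword blocks are preserved verbatim and logged,
never silently dropped.

Card layouts (fields in order):

    *NODE               nid(8), x(16), y(16), z(16)
    *ELEMENT_SOLID      eid, pid, n1..n8          (10 fields of 8)
    *PART               title line; then pid, secid, mid   (10-wide)
    *MAT_SIMPLIFIED_... card 1: mid, rho, km, mu, g, sigf
                        card 2: lcid, tbid, pr    (10-wide)
    *DEFINE_CURVE       card 1: lcid, sidr, sfa, sfo; then point lines a, o
    *DEFINE_TABLE       card 1: tbid; then lines rate, lcid
    *CONTROL_TIMESTEP   dtinit, tssfac, dt2ms
    *CONTROL_TERMINATION endtim

A negative dt2ms requests selective mass scaling to a step of |dt2ms|; a
blank/zero dt2ms means CFL-auto.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import material as mat_mod
from .fem import Mesh, SimulationConfig
from .material import FoamMaterial, LoadCurve, RateDependentFoam, RateTable
from .units import get_unit_system

log = logging.getLogger(__name__)

_MAT_ALIASES = (
    "*MAT_SIMPLIFIED_RUBBER/FOAM",
    "*MAT_SIMPLIFIED_FOAM",
    "*MAT_SIMPLIFIED_RUBBER",
    "*MAT_181",
)

_TISSUES = ("muscle", "soft", "cortical", "spongy")


class DeckError(ValueError):
    pass


@dataclass
class MatCard:
    mid: int
    rho: float
    km: float
    mu: float = 0.0
    g: float = 0.0
    sigf: float = 0.0
    lcid: int = 0
    tbid: int = 0
    pr: float = 0.3


@dataclass
class CurveCard:
    lcid: int
    sfa: float = 1.0
    sfo: float = 1.0
    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))


@dataclass
class PartCard:
    pid: int
    title: str = ""
    secid: int = 1
    mid: int = 0


@dataclass
class DeckSubset:
    nodes: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    solids: dict[int, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    parts: dict[int, PartCard] = field(default_factory=dict)
    mats: dict[int, MatCard] = field(default_factory=dict)
    curves: dict[int, CurveCard] = field(default_factory=dict)
    tables: dict[int, list[tuple[float, int]]] = field(default_factory=dict)
    dtinit: float = 0.0
    tssfac: float = 0.9
    dt2ms: float = 0.0
    endtim: float = 0.0
    extra: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for eid, (pid, conn) in self.solids.items():
            if pid not in self.parts:
                raise DeckError(f"element {eid} references missing part {pid}")
            for nid in conn:
                if nid not in self.nodes:
                    raise DeckError(f"element {eid} references missing node {nid}")
        for pid, part in self.parts.items():
            if part.mid not in self.mats:
                raise DeckError(f"part {pid} references missing material {part.mid}")
        for mid, mc in self.mats.items():
            if mc.lcid and mc.lcid not in self.curves:
                raise DeckError(f"material {mid} references missing curve {mc.lcid}")
            if mc.tbid and mc.tbid not in self.tables:
                raise DeckError(f"material {mid} references missing table {mc.tbid}")
            if not mc.lcid and not mc.tbid:
                raise DeckError(f"material {mid} has neither LC nor TBID")
        for tbid, rows in self.tables.items():
            for _, lcid in rows:
                if lcid not in self.curves:
                    raise DeckError(f"table {tbid} references missing curve {lcid}")


# ---------------------------------------------------------------------------
# parsing


def _fields(line: str, width: int, n: int | None = None) -> list[str]:
    if "," in line:
        parts = [p.strip() for p in line.split(",")]
    else:
        parts = [line[i : i + width].strip() for i in range(0, len(line), width)]
    if n is not None:
        parts = (parts + [""] * n)[:n]
    return parts


def _f(tok: str, default: float = 0.0) -> float:
    return float(tok) if tok else default


def _i(tok: str, default: int = 0) -> int:
    return int(float(tok)) if tok else default


def parse_deck(text: str) -> DeckSubset:
    """Parse a keyword deck subset from text."""
    deck = DeckSubset()
    lines = text.splitlines()
    blocks: list[tuple[str, list[str], int]] = []
    current: list[str] | None = None
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if line.startswith("$") or not line.strip():
            continue
        if line.startswith("*"):
            kw = line.strip().upper()
            current = []
            blocks.append((kw, current, lineno))
        elif current is not None:
            current.append(line)
        else:
            raise DeckError(f"line {lineno}: data before any keyword")

    for kw, body, lineno in blocks:
        try:
            _parse_block(deck, kw, body)
        except DeckError:
            raise
        except Exception as err:  # malformed card content
            raise DeckError(f"malformed {kw} card near line {lineno}: {err}") from err
    deck.validate()
    return deck


def _parse_block(deck: DeckSubset, kw: str, body: list[str]) -> None:
    if kw.startswith("*KEYWORD") or kw == "*END":
        return
    if kw == "*NODE":
        for line in body:
            if "," in line:
                toks = _fields(line, 8, 4)
            else:
                toks = [line[0:8].strip(), line[8:24].strip(),
                        line[24:40].strip(), line[40:56].strip()]
            deck.nodes[_i(toks[0])] = (_f(toks[1]), _f(toks[2]), _f(toks[3]))
    elif kw == "*ELEMENT_SOLID":
        for line in body:
            toks = _fields(line, 8, 10)
            eid, pid = _i(toks[0]), _i(toks[1])
            conn = tuple(_i(t) for t in toks[2:10])
            deck.solids[eid] = (pid, conn)
    elif kw == "*PART":
        i = 0
        while i < len(body):
            title = body[i].strip()
            if i + 1 >= len(body):
                raise DeckError("*PART title without id card")
            toks = _fields(body[i + 1], 10, 3)
            pid = _i(toks[0])
            deck.parts[pid] = PartCard(pid=pid, title=title,
                                       secid=_i(toks[1], 1), mid=_i(toks[2]))
            i += 2
    elif kw in _MAT_ALIASES:
        toks1 = _fields(body[0], 10, 6)
        toks2 = _fields(body[1], 10, 3) if len(body) > 1 else ["", "", ""]
        mid = _i(toks1[0])
        deck.mats[mid] = MatCard(
            mid=mid, rho=_f(toks1[1]), km=_f(toks1[2]), mu=_f(toks1[3]),
            g=_f(toks1[4]), sigf=_f(toks1[5]),
            lcid=_i(toks2[0]), tbid=_i(toks2[1]), pr=_f(toks2[2], 0.3),
        )
    elif kw == "*DEFINE_CURVE":
        toks = _fields(body[0], 10, 4)
        lcid = _i(toks[0])
        pts = []
        for line in body[1:]:
            p = _fields(line, 20, 2)
            pts.append((_f(p[0]), _f(p[1])))
        deck.curves[lcid] = CurveCard(
            lcid=lcid, sfa=_f(toks[2], 1.0) or 1.0, sfo=_f(toks[3], 1.0) or 1.0,
            points=np.array(pts),
        )
    elif kw == "*DEFINE_TABLE":
        toks = _fields(body[0], 10, 1)
        tbid = _i(toks[0])
        rows = []
        for line in body[1:]:
            p = _fields(line, 20, 2)
            rows.append((_f(p[0]), _i(p[1])))
        deck.tables[tbid] = rows
    elif kw == "*CONTROL_TIMESTEP":
        toks = _fields(body[0], 10, 3)
        deck.dtinit = _f(toks[0])
        deck.tssfac = _f(toks[1], 0.9) or 0.9
        deck.dt2ms = _f(toks[2])
    elif kw == "*CONTROL_TERMINATION":
        toks = _fields(body[0], 10, 1)
        deck.endtim = _f(toks[0])
    else:
        log.warning("ignoring unknown keyword %s (%d data lines, preserved)",
                    kw, len(body))
        deck.extra.append("\n".join([kw, *body]))


# ---------------------------------------------------------------------------
# writing (comma dialect)


def _r(x) -> str:
    return repr(float(x))


def write_deck(deck: DeckSubset) -> str:
    out = ["*KEYWORD"]
    if deck.endtim:
        out += ["*CONTROL_TERMINATION", _r(deck.endtim)]
    if deck.dtinit or deck.dt2ms:
        out += ["*CONTROL_TIMESTEP",
                f"{_r(deck.dtinit)},{_r(deck.tssfac)},{_r(deck.dt2ms)}"]
    if deck.nodes:
        out.append("*NODE")
        for nid in sorted(deck.nodes):
            x, y, z = deck.nodes[nid]
            out.append(f"{nid},{_r(x)},{_r(y)},{_r(z)}")
    if deck.solids:
        out.append("*ELEMENT_SOLID")
        for eid in sorted(deck.solids):
            pid, conn = deck.solids[eid]
            out.append(",".join(str(v) for v in (eid, pid, *conn)))
    for pid in sorted(deck.parts):
        p = deck.parts[pid]
        out += ["*PART", p.title or f"part {pid}",
                f"{p.pid},{p.secid},{p.mid}"]
    for mid in sorted(deck.mats):
        m = deck.mats[mid]
        out += ["*MAT_SIMPLIFIED_RUBBER/FOAM",
                f"{m.mid},{_r(m.rho)},{_r(m.km)},{_r(m.mu)},{_r(m.g)},{_r(m.sigf)}",
                f"{m.lcid},{m.tbid},{_r(m.pr)}"]
    for lcid in sorted(deck.curves):
        c = deck.curves[lcid]
        out += ["*DEFINE_CURVE", f"{c.lcid},0,{_r(c.sfa)},{_r(c.sfo)}"]
        out += [f"{_r(a)},{_r(o)}" for a, o in c.points]
    for tbid in sorted(deck.tables):
        out += ["*DEFINE_TABLE", str(tbid)]
        out += [f"{_r(r)},{lcid}" for r, lcid in deck.tables[tbid]]
    out.extend(deck.extra)
    out.append("*END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# deck -> solvable problem


def _load_curve(deck: DeckSubset, lcid: int, stress_factor: float,
                sfo_override: float | None) -> LoadCurve:
    c = deck.curves[lcid]
    sfo = sfo_override if sfo_override is not None else c.sfo
    return LoadCurve(
        strain=c.points[:, 0] * c.sfa,
        stress=c.points[:, 1] * stress_factor,
        sfo=sfo,
    )


def _part_label(title: str) -> dict:
    low = title.lower()
    tissue = next((t for t in _TISSUES if t in low), "other")
    side = "left" if "left" in low else "right" if "right" in low else "na"
    return {"tissue": tissue, "side": side, "title": title}


def build_problem(
    deck: DeckSubset,
    units: str = "mm_ms_kg",
    sfo_override: float | None = None,
    exponents=mat_mod.DEFAULT_EXPONENTS,
    allow_poor_fit: bool = False,
) -> tuple[Mesh, dict, SimulationConfig]:
    """Convert a parsed deck into SI mesh, materials and base config."""
    us = get_unit_system(units)
    deck.validate()

    nid_sorted = sorted(deck.nodes)
    nid_index = {nid: i for i, nid in enumerate(nid_sorted)}
    coords = np.array([deck.nodes[n] for n in nid_sorted]) * us.length

    eids = sorted(deck.solids)
    conn = np.array([[nid_index[n] for n in deck.solids[e][1]] for e in eids])
    epart = np.array([deck.solids[e][0] for e in eids])

    part_labels = {pid: _part_label(p.title) for pid, p in deck.parts.items()}
    mesh = Mesh(nodes=coords, elements=conn, element_part=epart,
                part_labels=part_labels)

    materials: dict[int, FoamMaterial | RateDependentFoam] = {}
    for pid in sorted(set(epart.tolist())):
        mc = deck.mats[deck.parts[pid].mid]
        kwargs = dict(
            density=mc.rho * us.density,
            bulk_modulus=mc.km * us.stress,
            shear_modulus=(mc.g or mc.km * 0.2) * us.stress,
            allow_poor_fit=allow_poor_fit,
        )
        if mc.tbid:
            # curve SFOs are intrinsic to the table; an override scales the
            # whole table response
            entries = []
            for rate, lcid in deck.tables[mc.tbid]:
                entries.append((rate * us.rate,
                                _load_curve(deck, lcid, us.stress, None)))
            table = RateTable(tuple(entries))
            mat = RateDependentFoam.from_table(
                table, mc.pr, sfo=sfo_override if sfo_override is not None
                else 1.0, exponents=exponents, **kwargs)
        else:
            # fit against the unscaled ordinates; the effective SFO acts as a
            # runtime multiplier so stress scales exactly with it
            c = deck.curves[mc.lcid]
            sfo = sfo_override if sfo_override is not None else c.sfo
            base = LoadCurve(strain=c.points[:, 0] * c.sfa,
                             stress=c.points[:, 1] * us.stress, sfo=1.0)
            mat = FoamMaterial.from_curve(
                base, mc.pr, sfo=sfo, exponents=exponents, **kwargs)
        mat.constants = _with_card_extras(mat.constants, mc)
        materials[pid] = mat

    config = SimulationConfig(
        termination=(deck.endtim or 1.0) * us.time,
        dt=deck.dtinit * us.time if deck.dtinit > 0 else None,
        dt2ms=abs(deck.dt2ms) * us.time if deck.dt2ms else None,
        safety=deck.tssfac if 0 < deck.tssfac <= 1 else 0.9,
        units=units,
    )
    return mesh, materials, config


def _with_card_extras(constants, mc: MatCard):
    from dataclasses import replace
    return replace(constants, damping_mu=mc.mu, limit_stress=mc.sigf)
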