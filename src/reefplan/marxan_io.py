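"""Reading and writing the Marxan dat-file dialect.

Four headered text files describe a planning instance (QMarxan-compatible
column names):

* ``pu.dat`` — ``id,cost,status``; status 0 = available, 2 = locked in
  (seed), 3 = locked out.
* ``spec.dat`` — ``id,target,spf,name``; absolute targets in feature units.
* ``puvspr.dat`` — ``species,pu,amount``, sorted by pu then species.
* ``bound.dat`` — ``id1,id2,boundary``; one row per undirected neighbour
  pair, shared edge length in metres.

Values are comma-separated on write; commas, tabs and runs of spaces are
all accepted on read. ``read_marxan_inputs(write_marxan_inputs(x))``
reproduces costs, statuses, targets, amounts and boundary lengths exactly.
"""

from __future__ import annotations

from pathlib import Path

from .objective import ScenarioConfig
from .seascape import Feature, FeatureTable
from .tessellation import PlanningUnit, PUStatus, Tessellation

_STATUS_TO_CODE = {PUStatus.AVAILABLE: 0, PUStatus.SEED: 2, PUStatus.LOCKOUT: 3}
_CODE_TO_STATUS = {0: PUStatus.AVAILABLE, 1: PUStatus.AVAILABLE,
                   2: PUStatus.SEED, 3: PUStatus.LOCKOUT}

FILES = ("pu.dat", "spec.dat", "puvspr.dat", "bound.dat")


class MarxanParseError(ValueError):
    """A dat file is malformed; the message carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _fmt(x: float) -> str:
    """Render a float compactly but losslessly (repr round-trips)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_marxan_inputs(
    tess: Tessellation,
    features: FeatureTable,
    scenario: ScenarioConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialize an instance to pu/spec/puvspr/bound dat files.

    Targets written to ``spec.dat`` are absolute amounts
    (``target_fraction * total_amount`` per feature). Returns the mapping
    of file kind to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in FILES}

    with open(paths["pu.dat"], "w") as fh:
        fh.write("id,cost,status\n")
        for u in tess.units:
            fh.write(f"{u.id},{_fmt(u.cost)},{_STATUS_TO_CODE[u.status]}\n")

    with open(paths["spec.dat"], "w") as fh:
        fh.write("id,target,spf,name\n")
        for f in features.features:
            target = scenario.target_for(f)
            fh.write(
                f"{f.id},{_fmt(target)},{_fmt(scenario.spf_for(f.id))},{f.name}\n"
            )

    rows = [
        (pu, f.id, amount)
        for f in features.features
        for pu, amount in features.amounts.get(f.id, {}).items()
    ]
    rows.sort()
    with open(paths["puvspr.dat"], "w") as fh:
        fh.write("species,pu,amount\n")
        for pu, fid, amount in rows:
            fh.write(f"{fid},{pu},{_fmt(amount)}\n")

    with open(paths["bound.dat"], "w") as fh:
        fh.write("id1,id2,boundary\n")
        for (a, b), length in sorted(tess.adjacency.items()):
            fh.write(f"{a},{b},{_fmt(length)}\n")
    return paths


def _parse(path: Path, columns: tuple[str, ...]):
    """Yield (lineno, fields) rows of a dat file, validating the header."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MarxanParseError(path, 1, "empty file, expected a header row")

    def split(line: str) -> list[str]:
        if "," in line:
            return [f.strip() for f in line.split(",")]
        return line.split()

    header = [h.lower() for h in split(lines[0])]
    missing = [c for c in columns if c not in header]
    if missing:
        raise MarxanParseError(
            path, 1, f"missing column(s) {missing}; header was {header}"
        )
    order = [header.index(c) for c in columns]
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = split(line)
        if len(fields) != len(header):
            raise MarxanParseError(
                path, lineno,
                f"expected {len(header)} fields, found {len(fields)}",
            )
        yield lineno, [fields[i] for i in order]


def _num(path: Path, lineno: int, raw: str, kind=float):
    try:
        return kind(raw)
    except ValueError:
        raise MarxanParseError(
            path, lineno, f"could not parse {kind.__name__} from '{raw}'"
        ) from None


def read_marxan_inputs(
    in_dir: str | Path,
) -> tuple[Tessellation, FeatureTable, ScenarioConfig]:
    """Load an instance from dat files.

    The returned tessellation is geometry-light: planning units are placed
    on a nominal grid (no real coordinates exist in the dat dialect) and
    every unit carries the full hexagon area for the nominal 15 m side, but
    costs, statuses, adjacency boundary lengths, feature amounts, absolute
    targets and SPFs are exactly those in the files. The scenario's
    ``target_fraction`` is reconstructed per feature as target/total.
    """
    in_dir = Path(in_dir)
    pu_path = in_dir / "pu.dat"
    units: list[PlanningUnit] = []
    side = 15.0
    from .tessellation import hexagon_area, M2_PER_HA

    area = hexagon_area(side) / M2_PER_HA
    for lineno, (pid, cost, status) in _parse(pu_path, ("id", "cost", "status")):
        code = _num(pu_path, lineno, status, int)
        if code not in _CODE_TO_STATUS:
            raise MarxanParseError(pu_path, lineno, f"unknown status code {code}")
        i = _num(pu_path, lineno, pid, int)
        units.append(
            PlanningUnit(
                id=i,
                centroid=(float(len(units) % 100) * 2 * side,
                          float(len(units) // 100) * 2 * side),
                area=area,
                cost=_num(pu_path, lineno, cost),
                status=_CODE_TO_STATUS[code],
            )
        )
    units.sort(key=lambda u: u.id)
    if [u.id for u in units] != list(range(1, len(units) + 1)):
        raise MarxanParseError(pu_path, 1, "pu ids are not contiguous from 1")
    n = len(units)
    tess = Tessellation(
        units=units,
        extent=(2 * side * 100.0, 2 * side * (n // 100 + 1)),
        side=side,
    )

    bound_path = in_dir / "bound.dat"
    for lineno, (a, b, length) in _parse(bound_path, ("id1", "id2", "boundary")):
        i = _num(bound_path, lineno, a, int)
        j = _num(bound_path, lineno, b, int)
        if not (1 <= i <= n and 1 <= j <= n):
            raise MarxanParseError(bound_path, lineno, f"unknown pu id in ({i},{j})")
        tess.adjacency[(min(i, j), max(i, j))] = _num(bound_path, lineno, length)

    spec_path = in_dir / "spec.dat"
    feat_meta: list[tuple[int, str, float, float]] = []  # id, name, target, spf
    for lineno, (fid, target, spf, name) in _parse(
        spec_path, ("id", "target", "spf", "name")
    ):
        feat_meta.append(
            (
                _num(spec_path, lineno, fid, int),
                name,
                _num(spec_path, lineno, target),
                _num(spec_path, lineno, spf),
            )
        )

    puvspr_path = in_dir / "puvspr.dat"
    amounts: dict[int, dict[int, float]] = {fid: {} for fid, *_ in feat_meta}
    for lineno, (fid, pu, amount) in _parse(
        puvspr_path, ("species", "pu", "amount")
    ):
        f = _num(puvspr_path, lineno, fid, int)
        p = _num(puvspr_path, lineno, pu, int)
        if f not in amounts:
            raise MarxanParseError(puvspr_path, lineno, f"unknown species id {f}")
        if not 1 <= p <= n:
            raise MarxanParseError(puvspr_path, lineno, f"unknown pu id {p}")
        amounts[f][p] = _num(puvspr_path, lineno, amount)

    features = FeatureTable(
        features=[
            Feature(id=fid, name=name,
                    total_amount=float(sum(amounts[fid].values())), spf=spf)
            for fid, name, _, spf in feat_meta
        ],
        amounts=amounts,
    )
    scenario = ScenarioConfig(
        name="from_files",
        absolute_targets={fid: target for fid, _, target, _ in feat_meta},
        spf={fid: spf for fid, _, _, spf in feat_meta},
    )
    return tess, features, scenario
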