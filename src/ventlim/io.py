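"""Readers and writers for the package's plain-text formats.

The declarative model file is UTF-8 with ``#`` comments and four sections:

    ## COMPARTMENTS   id, name, locality, taxon_class, biomass,
                      d13c_mean, d13c_sd, feeding_modes ('|'-separated)
    ## FLOWS          one ``source -> sink`` per line
    ## PARAMETERS     ``name = value`` or ``name = [lo, hi]``
    ## CONSTRAINTS    optional linear rows in flow labels, e.g.
                      ``Det->Bac + 0.5*DOC->Bac < 2.0``

Floats are written with ``repr`` so a write/read round trip reproduces the
model field-for-field. Ensembles are RFC-4180 CSV (flow labels as header,
17 significant digits) with a JSON metadata sidecar.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ModelParseError
from .model import (
    Compartment,
    ExtraConstraint,
    FoodWebModel,
    PhysiologyRules,
    SiteEnvironment,
    TaxonClassRules,
    build_topology,
)
from .sample import FlowEnsemble

_SECTIONS = ("COMPARTMENTS", "FLOWS", "PARAMETERS", "CONSTRAINTS")
_FLOW_TERM = re.compile(
    r"(?P<sign>[+-])?\s*(?:(?P<coef>\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*\*\s*)?"
    r"(?P<label>[A-Za-z_]\w*->[A-Za-z_]\w*)"
)


def _fmt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_model(model: FoodWebModel, path: str | Path, header_note: str | None = None) -> None:
    """Serialise a model; refuses to leave a partial file on error."""
    buf = _io.StringIO()
    buf.write("# ventlim model file\n")
    if header_note:
        for line in header_note.splitlines():
            buf.write(f"# {line}\n")
    buf.write("\n## COMPARTMENTS\n")
    buf.write("# id, name, locality, taxon_class, biomass, d13c_mean, d13c_sd, feeding_modes\n")
    w = csv.writer(buf, lineterminator="\n")
    for c in model.compartments:
        w.writerow([
            c.id, c.name, c.locality, c.taxon_class,
            _fmt(c.biomass), _fmt(c.d13c_mean), _fmt(c.d13c_sd),
            "|".join(sorted(c.feeding_modes)),
        ])
    buf.write("\n## FLOWS\n")
    for fl in model.flows:
        buf.write(f"{fl.source} -> {fl.sink}\n")
    buf.write("\n## PARAMETERS\n")
    env = model.environment
    if env is not None:
        buf.write(f"site_id = {env.site_id}\n")
        buf.write(f"depth = {_fmt(env.depth)}\n")
        buf.write(f"temperature = {_fmt(env.temperature)}\n")
        if env.advection is not None:
            buf.write(f"advection = {_fmt(env.advection)}\n")
        if env.scoc_range is not None:
            buf.write(f"scoc = [{_fmt(env.scoc_range[0])}, {_fmt(env.scoc_range[1])}]\n")
        if env.poc_range is not None:
            buf.write(f"poc = [{_fmt(env.poc_range[0])}, {_fmt(env.poc_range[1])}]\n")
        for chem, conc in env.substrate_conc.items():
            buf.write(f"substrate.{chem} = {_fmt(conc)}\n")
    r = model.rules
    buf.write(f"q10 = {_fmt(r.q10)}\n")
    for name in ("bge", "viral_lysis", "chemo_efficiency", "burial_efficiency", "doc_efflux"):
        lo, hi = getattr(r, f"{name}_range")
        buf.write(f"{name} = [{_fmt(lo)}, {_fmt(hi)}]\n")
    for cls_name in ("macrofauna", "megafauna"):
        cls = getattr(r, cls_name)
        for attr, key in (
            ("growth_coeff_range", "growth"), ("nge_range", "nge"), ("ae_range", "ae"),
            ("faecal_range", "faecal"), ("respiration_multiplier_range", "respiration_multiplier"),
        ):
            lo, hi = getattr(cls, attr)
            buf.write(f"{cls_name}.{key} = [{_fmt(lo)}, {_fmt(hi)}]\n")
        buf.write(f"{cls_name}.maintenance = {_fmt(cls.maintenance_coeff)}\n")
        buf.write(f"{cls_name}.bsr = {_fmt(cls.biomass_specific_respiration)}\n")
    if model.extra_constraints:
        buf.write("\n## CONSTRAINTS\n")
        for coeffs, op, rhs in model.extra_constraints:
            terms = []
            for i, (lab, coef) in enumerate(coeffs.items()):
                sign = "-" if coef < 0 else ("+" if i else "")
                mag = abs(coef)
                term = lab if mag == 1.0 else f"{repr(mag)}*{lab}"
                terms.append(f"{sign} {term}".strip() if i else f"{sign}{term}")
            buf.write(f"{' '.join(terms)} {op} {repr(float(rhs))}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _parse_number(text: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ModelParseError(f"expected a number, got {text!r}", lineno)


def _parse_value(text: str, lineno: int):
    text = text.strip()
    if text.startswith("["):
        if not text.endswith("]"):
            raise ModelParseError(f"unterminated range {text!r}", lineno)
        parts = [p.strip() for p in text[1:-1].split(",")]
        if len(parts) != 2:
            raise ModelParseError(f"range needs exactly two values: {text!r}", lineno)
        return (_parse_number(parts[0], lineno), _parse_number(parts[1], lineno))
    try:
        return float(text)
    except ValueError:
        return text  # strings (site_id) pass through


def parse_constraint_line(line: str, lineno: int) -> ExtraConstraint:
    """Parse one linear constraint like ``Det->Bac + 0.5*DOC->Bac < 2.0``."""
    masked = line.replace("->", "\x00")
    op = None
    for candidate in ("=", "<", ">"):
        if candidate in masked:
            op = candidate
            break
    if op is None:
        raise ModelParseError("constraint needs one of = < >", lineno)
    lhs_masked, _, rhs_masked = masked.partition(op)
    lhs = lhs_masked.replace("\x00", "->")
    rhs = _parse_number(rhs_masked.replace("\x00", "->").strip(), lineno)
    coeffs: dict[str, float] = {}
    consumed = 0
    for m in _FLOW_TERM.finditer(lhs):
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        if m.group("sign") == "-":
            coef = -coef
        lab = m.group("label")
        coeffs[lab] = coeffs.get(lab, 0.0) + coef
        consumed += len(m.group(0).strip())
    leftover = re.sub(r"[\s+\-]", "", _FLOW_TERM.sub("", lhs))
    if leftover:
        raise ModelParseError(f"could not parse constraint terms near {leftover!r}", lineno)
    if not coeffs:
        raise ModelParseError("constraint has no flow terms", lineno)
    return (coeffs, op, float(rhs))


def read_model(path: str | Path) -> FoodWebModel:
    """Parse and validate a declarative model file."""
    text = Path(path).read_text(encoding="utf-8")
    section = None
    compartments: list[Compartment] = []
    flows: list[tuple[str, str]] = []
    params: dict[str, object] = {}
    constraints: list[ExtraConstraint] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.strip().startswith("##"):
            name = raw.strip().lstrip("#").strip().upper()
            if name not in _SECTIONS:
                raise ModelParseError(f"unknown section {name!r}", lineno)
            section = name
            continue
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if section == "COMPARTMENTS":
            row = next(csv.reader([line]))
            if len(row) < 4:
                raise ModelParseError("compartment row needs at least id, name, locality, taxon_class", lineno)
            row = [cell.strip() for cell in row] + [""] * (8 - len(row))
            def opt(cell: str) -> float | None:
                return None if cell == "" else _parse_number(cell, lineno)
            try:
                compartments.append(Compartment(
                    id=row[0], name=row[1], locality=row[2], taxon_class=row[3],
                    biomass=opt(row[4]), d13c_mean=opt(row[5]), d13c_sd=opt(row[6]),
                    feeding_modes=frozenset(m for m in row[7].split("|") if m),
                ))
            except Exception as exc:
                raise ModelParseError(str(exc), lineno)
        elif section == "FLOWS":
            if "->" not in line:
                raise ModelParseError(f"flow line must be 'source -> sink', got {line!r}", lineno)
            src, _, snk = line.partition("->")
            flows.append((src.strip(), snk.strip()))
        elif section == "PARAMETERS":
            if "=" not in line:
                raise ModelParseError(f"parameter line must be 'name = value', got {line!r}", lineno)
            key, _, value = line.partition("=")
            params[key.strip()] = _parse_value(value, lineno)
        elif section == "CONSTRAINTS":
            constraints.append(parse_constraint_line(line, lineno))
        else:
            raise ModelParseError("content before any section header", lineno)
    if not compartments:
        raise ModelParseError("no COMPARTMENTS section")
    env = _environment_from_params(params)
    rules = _rules_from_params(params)
    try:
        return build_topology(
            compartments,
            flow_list=flows if flows else None,
            environment=env,
            rules=rules,
            extra_constraints=constraints,
        )
    except Exception as exc:
        raise ModelParseError(str(exc))


def _environment_from_params(params: dict) -> SiteEnvironment | None:
    keys = ("site_id", "depth", "temperature")
    if not any(k in params for k in keys):
        return None
    missing = [k for k in keys if k not in params]
    if missing:
        raise ModelParseError(f"site parameters incomplete; missing {missing}")
    substrates = {
        k.split(".", 1)[1]: float(v) for k, v in params.items() if k.startswith("substrate.")
    }
    def rng(key):
        v = params.get(key)
        return tuple(v) if v is not None else None
    return SiteEnvironment(
        site_id=str(params["site_id"]),
        depth=float(params["depth"]),
        temperature=float(params["temperature"]),
        scoc_range=rng("scoc"),
        poc_range=rng("poc"),
        advection=float(params["advection"]) if "advection" in params else None,
        substrate_conc=substrates,
    )


def _rules_from_params(params: dict) -> PhysiologyRules:
    defaults = PhysiologyRules()
    kwargs: dict = {}
    if "q10" in params:
        kwargs["q10"] = float(params["q10"])
    for name in ("bge", "viral_lysis", "chemo_efficiency", "burial_efficiency", "doc_efflux"):
        if name in params:
            kwargs[f"{name}_range"] = tuple(params[name])
    for cls_name in ("macrofauna", "megafauna"):
        base = getattr(defaults, cls_name)
        cls_kwargs: dict = {}
        mapping = {
            "growth": "growth_coeff_range", "nge": "nge_range", "ae": "ae_range",
            "faecal": "faecal_range", "respiration_multiplier": "respiration_multiplier_range",
        }
        for key, attr in mapping.items():
            p = params.get(f"{cls_name}.{key}")
            if p is not None:
                cls_kwargs[attr] = tuple(p)
        if f"{cls_name}.maintenance" in params:
            cls_kwargs["maintenance_coeff"] = float(params[f"{cls_name}.maintenance"])
        if f"{cls_name}.bsr" in params:
            cls_kwargs["biomass_specific_respiration"] = float(params[f"{cls_name}.bsr"])
        if cls_kwargs:
            kwargs[cls_name] = TaxonClassRules(**{
                **{f.name: getattr(base, f.name) for f in base.__dataclass_fields__.values()},
                **cls_kwargs,
            })
    return PhysiologyRules(**kwargs) if kwargs else defaults


# ----------------------------------------------------------------------
# Ensembles, stocks and reports
# ----------------------------------------------------------------------

def write_ensemble(ensemble: FlowEnsemble, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(ensemble.flow_labels) + "\r\n")
        np.savetxt(fh, ensemble.samples, fmt="%.17g", delimiter=",", newline="\r\n")
    meta = {
        "seed": ensemble.seed,
        "n_burn_in": ensemble.n_burn_in,
        "jump_length": ensemble.jump_length,
        "n_iterations_requested": ensemble.n_iterations_requested,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8"
    )


def read_ensemble(path: str | Path) -> FlowEnsemble:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        labels = header.split(",")
        samples = np.loadtxt(fh, delimiter=",", ndmin=2)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    else:
        meta = {"seed": -1, "n_burn_in": 0, "jump_length": 0.0,
                "n_iterations_requested": samples.shape[0]}
    return FlowEnsemble(
        samples=samples,
        flow_labels=labels,
        seed=int(meta["seed"]),
        n_burn_in=int(meta["n_burn_in"]),
        jump_length=float(meta["jump_length"]),
        n_iterations_requested=int(meta["n_iterations_requested"]),
    )


def write_stocks_csv(model: FoodWebModel, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compartment_id", "biomass", "d13c_mean", "d13c_sd"])
        for c in model.compartments:
            if c.is_internal:
                w.writerow([c.id, _fmt(c.biomass), _fmt(c.d13c_mean), _fmt(c.d13c_sd)])


def read_stocks_csv(path: str | Path) -> dict[str, dict[str, float | None]]:
    out: dict[str, dict[str, float | None]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["compartment_id"]] = {
                key: (float(row[key]) if row.get(key) else None)
                for key in ("biomass", "d13c_mean", "d13c_sd")
            }
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """Run settings; the defaults follow the production sampling protocol
    (100 000 iterations, 2% convergence tolerance, the standard run-length
    ladder)."""

    n_iterations: int = 100_000
    seed: int = 0
    burn_in: int = 1000
    jump_length: float | None = None
    tolerance: float = 1e-8
    convergence_tolerance: float = 0.02
    run_lengths: tuple[int, ...] = (300, 3_000, 30_000, 200_000)
    isotope_discrimination: float = 1.0
    isotope_tolerance_sd: float = 2.0
    tlim_mode: str = "exact"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ModelParseError(f"unknown config keys: {sorted(unknown)}")
        if "run_lengths" in data:
            data["run_lengths"] = tuple(int(x) for x in data["run_lengths"])
        return cls(**data)

    def updated(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return RunConfig(**{**self.__dict__, **clean})
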