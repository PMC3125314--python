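"""YAML model schema and serialization.

Top-level keys: ``name``, ``states``, ``inputs``, ``terms``, ``notes``.
Each term: ``name``, ``target`` (state name), ``kind`` (a|b|c|d), ``tag``,
optional ``arg`` (state/input name, or ``{total: <const>, minus: [names]}``
for affine arguments in reduced models), ``mult``, ``modulators``
(``[{arg, tag}]``), ``saturating_flux``, ``coupling``, ``family``,
``a5_flag``.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .model import AffineArg, NetworkModel, Term, validate_model
from .tags import PropertyTag

__all__ = ["read_model", "write_model", "model_from_dict", "model_to_dict",
           "load_packaged_model", "SchemaError"]


class SchemaError(ValueError):
    pass


def _parse_tag(value, where: str) -> PropertyTag:
    try:
        return PropertyTag(value)
    except ValueError:
        raise SchemaError(
            f"{where}: unknown tag {value!r}; valid tags: "
            f"{[t.value for t in PropertyTag]}") from None


def _parse_ref(value, model_names: dict, where: str):
    if value is None:
        return None
    if isinstance(value, dict):
        if "total" not in value or "minus" not in value:
            raise SchemaError(f"{where}: affine arg needs 'total' and 'minus'")
        idx = []
        for nm in value["minus"]:
            if nm not in model_names:
                raise SchemaError(f"{where}: unknown state {nm!r} in affine arg")
            idx.append(model_names[nm])
        return AffineArg(total=str(value["total"]), subtract=tuple(idx))
    if value not in model_names:
        raise SchemaError(f"{where}: unknown state/input {value!r}")
    return model_names[value]


def model_from_dict(data: dict) -> NetworkModel:
    if "states" not in data or not data["states"]:
        raise SchemaError("model needs a nonempty 'states' list")
    states = tuple(str(s) for s in data["states"])
    inputs = tuple(str(s) for s in data.get("inputs") or ())
    names = {s: i for i, s in enumerate(states)}
    names.update({u: len(states) + i for i, u in enumerate(inputs)})

    terms = []
    for k, td in enumerate(data.get("terms") or ()):
        where = f"terms[{k}] ({td.get('name', '?')})"
        if "target" not in td or td["target"] not in names:
            raise SchemaError(f"{where}: missing or unknown target")
        target = names[td["target"]]
        if target >= len(states):
            raise SchemaError(f"{where}: target must be a state, not an input")
        kind = td.get("kind")
        if kind not in ("a", "b", "c", "d"):
            raise SchemaError(f"{where}: kind must be one of a, b, c, d")
        tag = _parse_tag(td.get("tag"), where)
        mods = tuple(
            (_parse_ref(m.get("arg"), names, where + " modulator"),
             _parse_tag(m.get("tag"), where + " modulator"))
            for m in td.get("modulators") or ())
        terms.append(Term(
            name=str(td.get("name", f"{kind}{k}")),
            target=target,
            kind=kind,
            tag=tag,
            arg=_parse_ref(td.get("arg"), names, where),
            mult=_parse_ref(td.get("mult"), names, where),
            modulators=mods,
            saturating_flux=bool(td.get("saturating_flux", False)),
            coupling_id=td.get("coupling"),
            family=td.get("family"),
            a5_flag=bool(td.get("a5_flag", False)),
        ))
    return NetworkModel(state_names=states, input_names=inputs,
                        terms=tuple(terms), notes=str(data.get("notes", "")),
                        name=str(data.get("name", "")))


def model_to_dict(model: NetworkModel) -> dict:
    def ref_out(ref):
        if ref is None:
            return None
        if isinstance(ref, AffineArg):
            return {"total": ref.total,
                    "minus": [model.var_name(i) for i in ref.subtract]}
        return model.var_name(ref)

    terms = []
    for t in model.terms:
        td = {"name": t.name, "target": model.state_names[t.target],
              "kind": t.kind, "tag": t.tag.value}
        if t.arg is not None:
            td["arg"] = ref_out(t.arg)
        if t.mult is not None:
            td["mult"] = ref_out(t.mult)
        if t.modulators:
            td["modulators"] = [{"arg": ref_out(m), "tag": mt.value}
                                for m, mt in t.modulators]
        if t.saturating_flux:
            td["saturating_flux"] = True
        if t.coupling_id:
            td["coupling"] = t.coupling_id
        if t.family:
            td["family"] = t.family
        if t.a5_flag:
            td["a5_flag"] = True
        terms.append(td)
    return {"name": model.name, "states": list(model.state_names),
            "inputs": list(model.input_names), "terms": terms,
            "notes": model.notes}


def read_model(path) -> NetworkModel:
    """Load and validate a model; raises SchemaError / StructuralError on a
    malformed file and ValueError on assumption violations."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    model = model_from_dict(data)
    report = validate_model(model)
    if not report:
        raise ValueError(f"model {model.name!r} violates assumptions: "
                         f"{report.diagnostics}")
    return model


def write_model(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_packaged_model(name: str) -> NetworkModel:
    """Load one of the shipped models from ``robnet/models/<name>.yaml``."""
    ref = resources.files("robnet") / "models" / f"{name}.yaml"
    with ref.open() as fh:
        data = yaml.safe_load(fh)
    model = model_from_dict(data)
    report = validate_model(model)
    if not report:  # pragma: no cover - packaged models are valid
        raise ValueError(f"packaged model {name!r} invalid: {report.diagnostics}")
    return model
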