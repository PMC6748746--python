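"""Model readers and writers: SBML Level 3 + FBC v2, and the COBRA-style
JSON dialect.

The JSON dialect is the package's canonical on-disk form (sorted keys,
id-ordered lists, fixed indentation), chosen for version-control
friendliness: re-saving an unchanged model is byte-identical.  SBML
import/export targets L3V1 with the FBC v2 extension via COBRApy's
libsbml machinery; older dialects are read best-effort and never
written.  Round trips are functionally lossless: id sets, bounds, gene
associations and the FBA optimum are preserved.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import jsonschema
import libsbml

from .errors import IOFormatError
from .model import Model
from .serialize import (
    METABOLITE_RECORD_SCHEMA,
    REACTION_RECORD_SCHEMA,
    canonical_dumps,
    model_from_dict,
    model_to_dict,
)

MODEL_SCHEMA = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "Constraint-based model, COBRA-style JSON dialect",
    "type": "object",
    "required": ["reactions", "metabolites"],
    "properties": {
        "id": {"type": "string"},
        "version": {"type": "string"},
        "objective_direction": {"enum": ["max", "min"]},
        "metabolites": {"type": "array", "items": METABOLITE_RECORD_SCHEMA},
        "reactions": {"type": "array", "items": REACTION_RECORD_SCHEMA},
        "genes": {
            "type": "array",
            "items": {"type": "object", "required": ["id"]},
        },
    },
}

_KNOWN_TOP_LEVEL = {
    "id",
    "name",
    "version",
    "objective_direction",
    "metabolites",
    "reactions",
    "genes",
    "compartments",
    "notes",
    "annotation",
}


def write_json_model(model: Model, path) -> None:
    """Write the canonical JSON form; byte-stable for unchanged models."""
    model.validate()
    Path(path).write_text(canonical_dumps(model_to_dict(model)))


def read_json_model(path) -> Model:
    """Read a model in the COBRA-style JSON dialect.

    Schema violations raise :class:`IOFormatError` with the JSON-pointer
    location; unknown top-level keys only warn (forward compatibility).
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IOFormatError(f"{path} is not valid JSON: {exc}") from exc
    validator = jsonschema.Draft202012Validator(MODEL_SCHEMA)
    errors = sorted(validator.iter_errors(data), key=lambda e: list(e.absolute_path))
    if errors:
        first = errors[0]
        pointer = "/" + "/".join(str(p) for p in first.absolute_path)
        raise IOFormatError(
            f"{path} violates the model schema at {pointer!r}: {first.message}"
        )
    unknown = set(data) - _KNOWN_TOP_LEVEL
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown top-level keys {sorted(unknown)}",
            stacklevel=2,
        )
    try:
        return model_from_dict(data)
    except Exception as exc:
        raise IOFormatError(f"cannot build model from {path}: {exc}") from exc


def _precheck_sbml(path: Path) -> None:
    """Raise informative errors for malformed XML or non-FBC SBML."""
    document = libsbml.readSBMLFromFile(str(path))
    fatal = []
    for i in range(document.getNumErrors()):
        err = document.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            fatal.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if fatal:
        raise IOFormatError(
            f"{path} is not parseable SBML:\n" + "\n".join(fatal[:5])
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise IOFormatError(f"{path} contains no SBML model element")
    if sbml_model.getPlugin("fbc") is None:
        raise IOFormatError(
            f"{path} has no FBC package information; constraint-based models "
            "require SBML Level 3 with the FBC extension (flux bounds, "
            "objectives and gene-product associations)"
        )


def read_sbml(path) -> Model:
    """Read an SBML L3+FBC model (species, stoichiometry, FBC bounds,
    AND/OR gene-product associations, FBC objective)."""
    import cobra.io

    from .cobra_bridge import from_cobra

    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    _precheck_sbml(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(str(path))
    except IOFormatError:
        raise
    except Exception as exc:
        raise IOFormatError(f"cannot read SBML model {path}: {exc}") from exc
    return from_cobra(cm)


def write_sbml(model: Model, path) -> None:
    """Write SBML Level 3 Version 1 with FBC v2."""
    import cobra.io

    from .cobra_bridge import to_cobra

    try:
        cobra.io.write_sbml_model(to_cobra(model), str(path))
    except Exception as exc:
        raise IOFormatError(f"cannot write SBML model to {path}: {exc}") from exc


_READERS = {".json": read_json_model, ".xml": read_sbml, ".sbml": read_sbml}


def read_model(path) -> Model:
    """Dispatch on file suffix: ``.json`` → JSON dialect, ``.xml``/``.sbml``
    → SBML."""
    suffix = Path(path).suffix.lower()
    reader = _READERS.get(suffix)
    if reader is None:
        raise IOFormatError(
            f"unsupported model file suffix {suffix!r} (expected .json, .xml "
            "or .sbml)"
        )
    return reader(path)


def write_model(model: Model, path, format=None) -> None:
    """Write a model; format from the explicit argument or the suffix."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = {"json": "json", ".json": "json", ".xml": "sbml", ".sbml": "sbml"}.get(
            suffix
        )
    if format == "json":
        write_json_model(model, path)
    elif format == "sbml":
        write_sbml(model, path)
    else:
        raise IOFormatError(f"unsupported model format {format!r}")
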