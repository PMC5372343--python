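"""Minimal structural validation of the shipped JSON report schemas.

Supports the subset of JSON-Schema keywords the shipped schemas use
(type, properties, required, items); enough to round-trip-check emitted
reports without an external validator dependency.
"""

from __future__ import annotations

import json
from importlib import resources

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


class SchemaError(ValueError):
    """Document does not conform to the schema."""


def load_schema(name: str) -> dict:
    """Load a schema shipped with the package ('truth' or 'report')."""
    path = resources.files("panscaf") / "schemas" / f"{name}.schema.json"
    return json.loads(path.read_text())


def validate(obj, schema: dict, path: str = "$") -> None:
    """Raise SchemaError where ``obj`` violates ``schema``."""
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        py = tuple(t for name in allowed for t in (
            _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)))
        if not isinstance(obj, py) or (isinstance(obj, bool) and bool not in py):
            raise SchemaError(f"{path}: expected {typ}, got {type(obj).__name__}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise SchemaError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                validate(obj[key], sub, f"{path}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            validate(item, schema["items"], f"{path}[{i}]")
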