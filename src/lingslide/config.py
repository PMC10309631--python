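"""Flat key-value configuration files and provenance headers.

A config is plain text, one ``key = value`` per line, ``#`` comments.
Model keys: mu, a, s_A, s_B, I_wA, I_wB, I_Aw, I_Bw; initial state keys
x_A0, x_B0, w0; control-regime keys carry a ``ctrl_`` prefix; the
endangerment threshold is ET.  The same flat mapping is echoed into every
output file as a provenance header.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["read_config", "write_config", "provenance_lines"]


def _parse_value(raw: str):
    raw = raw.strip()
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    if "," in raw:
        # comma-separated numbers become a tuple; free text stays a string
        parts = [p.strip() for p in raw.split(",")]
        try:
            return tuple(float(p) for p in parts)
        except ValueError:
            return raw
    return raw


def read_config(path: str | Path) -> dict:
    """Parse a flat key-value config file into a dict."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = line.split("=", 1)
        out[key.strip()] = _parse_value(raw)
    return out


def _format_value(value) -> str:
    if isinstance(value, (tuple, list)):
        return ", ".join(_format_value(v) for v in value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_config(path: str | Path, mapping: dict) -> None:
    """Write a dict as a flat key-value config file."""
    lines = [f"{k} = {_format_value(v)}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def provenance_lines(mapping: dict, prefix: str = "# ") -> list[str]:
    """Comment lines echoing a full parameter mapping, for output headers."""
    from . import __version__

    lines = [f"{prefix}lingslide {__version__}"]
    lines += [f"{prefix}{k} = {_format_value(v)}" for k, v in mapping.items()]
    return lines
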