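"""Canonical molecular-descriptor naming.

Descriptor names arrive from several sources (tabular headers, published
feature panels) with inconsistent separators ("ETA BetaP s" vs
"ETA_BetaP_s") and the occasional transcription slip.  Every name entering
the pipeline is passed through :func:`normalize_name` so that set
operations over descriptors (panel unions, feature lookups) are exact.
"""

from __future__ import annotations

# Known transcription variants -> canonical spelling.  "MEDC-23" appears in
# one published activity panel where every other source prints "MDEC-23"
# (molecular distance edge between secondary and tertiary carbons).
DEFAULT_ALIASES: dict[str, str] = {
    "MEDC-23": "MDEC-23",
}


def normalize_name(raw: str, aliases: dict[str, str] | None = None) -> str:
    """Return the canonical form of a descriptor name.

    Leading/trailing whitespace is trimmed, internal whitespace runs are
    collapsed to single underscores, and the alias table is applied.  Case
    is preserved: descriptor names are case-sensitive identifiers
    (``SsOH`` and ``SHsOH`` are different descriptors).

    Parameters
    ----------
    raw : str
        Name as it appears in the source.
    aliases : dict, optional
        Alias table to apply after whitespace normalization; defaults to
        :data:`DEFAULT_ALIASES`.

    Raises
    ------
    ValueError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str):
        raise ValueError(f"descriptor name must be a string, got {type(raw).__name__}")
    collapsed = "_".join(raw.split())
    if not collapsed:
        raise ValueError("descriptor name is empty")
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(collapsed, collapsed)


def normalize_names(raw_names, aliases: dict[str, str] | None = None) -> list[str]:
    """Normalize a sequence of names, preserving order."""
    return [normalize_name(n, aliases) for n in raw_names]
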