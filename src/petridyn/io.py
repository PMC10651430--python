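"""Native text serialization for Pathway Petri Nets.

The ``.ppn`` format is a line-oriented, versioned document with explicit
sections.  It retains everything the net carries — typed weighted arcs,
kinetic constants, initial marking, display names — which a stoichiometric
matrix could not::

    ppn 1
    [places]
    A 2.0
    B 0.0
    [transitions]
    r1 0.5
    [arcs]
    A r1 reactant 1
    r1 B product 1
    [names]
    A | species A

``[places]`` lines are ``<id> <initial concentration>``, ``[transitions]``
lines ``<id> <mass-action rate constant>``, ``[arcs]`` lines
``<source> <target> <role> [weight]`` (weight defaults to 1), ``[names]``
lines ``<id> | <free text>``.  ``#`` starts a comment (except inside a
display name's free text); blank lines are ignored.  Identifiers are
case-sensitive and whitespace-free.
"""

from __future__ import annotations

from pathlib import Path

from .core import PPN, Arc, KineticLaw, ValidationError, validate

__all__ = ["FormatError", "read_ppn", "write_ppn", "dumps_ppn", "loads_ppn"]

FORMAT_VERSION = 1
_SECTIONS = ("places", "transitions", "arcs", "names")


class FormatError(ValueError):
    """Raised on a malformed ``.ppn`` document; names the offending line."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def loads_ppn(text: str) -> PPN:
    """Parse a ``.ppn`` document from a string.

    Raises :class:`FormatError` on syntax problems and
    :class:`~petridyn.core.ValidationError` (listing all violations) when
    the parsed net breaks a structural invariant.
    """
    lines = text.splitlines()
    if not lines:
        raise FormatError(1, "empty document")
    header = lines[0].split("#", 1)[0].strip().split()
    if len(header) != 2 or header[0] != "ppn":
        raise FormatError(1, "expected header 'ppn <version>'")
    try:
        version = int(header[1])
    except ValueError:
        raise FormatError(1, f"bad version {header[1]!r}") from None
    if version != FORMAT_VERSION:
        raise FormatError(1, f"unsupported format version {version}")

    ppn = PPN()
    section: str | None = None
    for lineno, raw in enumerate(lines[1:], start=2):
        # '#' comments apply everywhere except inside display names,
        # which are free text after the '|'
        if section == "names" and not raw.lstrip().startswith("#"):
            line = raw.strip()
        else:
            line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in _SECTIONS:
                raise FormatError(lineno, f"unknown section [{section}]")
            continue
        if section is None:
            raise FormatError(lineno, "content before any section header")
        if section == "places":
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(lineno, "place line must be '<id> <concentration>'")
            try:
                conc = float(parts[1])
            except ValueError:
                raise FormatError(lineno, f"bad concentration {parts[1]!r}") from None
            ppn.places.add(parts[0])
            ppn.initial_marking[parts[0]] = conc
        elif section == "transitions":
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(lineno, "transition line must be '<id> <rate constant>'")
            try:
                k = float(parts[1])
            except ValueError:
                raise FormatError(lineno, f"bad rate constant {parts[1]!r}") from None
            ppn.transitions.add(parts[0])
            ppn.kinetics[parts[0]] = KineticLaw(rate_constant=k)
        elif section == "arcs":
            parts = line.split()
            if len(parts) not in (3, 4):
                raise FormatError(lineno, "arc line must be '<source> <target> <role> [weight]'")
            weight = 1
            if len(parts) == 4:
                try:
                    weight = int(parts[3])
                except ValueError:
                    raise FormatError(lineno, f"bad weight {parts[3]!r}") from None
            ppn.arcs.add(Arc(parts[0], parts[1], parts[2], weight))
        elif section == "names":
            if "|" not in line:
                raise FormatError(lineno, "name line must be '<id> | <display name>'")
            ident, name = line.split("|", 1)
            ppn.display_names[ident.strip()] = name.strip()

    violations = validate(ppn)
    if violations:
        raise ValidationError(violations)
    return ppn


def read_ppn(path: str | Path) -> PPN:
    """Read and validate a PPN from a ``.ppn`` file."""
    return loads_ppn(Path(path).read_text())


def dumps_ppn(ppn: PPN) -> str:
    """Serialize a PPN to the native format (deterministic ordering)."""
    out = [f"ppn {FORMAT_VERSION}"]
    out.append("[places]")
    for p in sorted(ppn.places):
        out.append(f"{p} {ppn.initial_marking.get(p, 0.0)!r}")
    out.append("[transitions]")
    for t in sorted(ppn.transitions):
        out.append(f"{t} {ppn.kinetics[t].rate_constant!r}")
    out.append("[arcs]")
    for a in sorted(ppn.arcs):
        out.append(f"{a.source} {a.target} {a.role} {a.weight}")
    if ppn.display_names:
        out.append("[names]")
        for ident in sorted(ppn.display_names):
            out.append(f"{ident} | {ppn.display_names[ident]}")
    return "\n".join(out) + "\n"


def write_ppn(ppn: PPN, path: str | Path) -> None:
    """Write a PPN to ``path``; ``read_ppn(write_ppn(p))`` is identity."""
    Path(path).write_text(dumps_ppn(ppn))
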