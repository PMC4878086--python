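"""Exception hierarchy shared across the package."""


class MeshKosError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MeshKosError, ValueError):
    """Malformed input record; the message names the offending line or element."""


class IntegrityError(MeshKosError, ValueError):
    """Input violates a structural invariant (duplicate identifiers, conflicting labels...)."""


class UnknownTermError(MeshKosError, LookupError):
    """A term failed to resolve against the vocabulary."""


class DegenerateInputError(MeshKosError, ValueError):
    """Input is structurally valid but the operation is undefined on it (e.g. zero vectors)."""
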