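"""Exception hierarchy for igkit."""


class IgkitError(Exception):
    """Base class for all igkit errors."""


class GermlineError(IgkitError):
    """Malformed or invalid germline reference data."""


class AnnotationError(IgkitError):
    """A read could not be annotated."""


class InputError(IgkitError):
    """Invalid user input (paths, tables, configuration)."""
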