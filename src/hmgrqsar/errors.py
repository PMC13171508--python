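"""Exception hierarchy shared across the pipeline stages."""


class HmgrQsarError(Exception):
    """Base class for all package errors."""


class StructureError(HmgrQsarError):
    """A SMILES string could not be parsed into a valid molecule."""

    def __init__(self, smiles: str, detail: str = "") -> None:
        self.smiles = smiles
        msg = f"invalid structure: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConfigurationError(HmgrQsarError):
    """Invalid user configuration (columns, thresholds, profiles, grids)."""


class LibraryError(HmgrQsarError):
    """A fragment library entry violates the one-attachment-point contract."""


class IntegrityError(HmgrQsarError):
    """A generated dataset and its ground-truth ledger disagree."""
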