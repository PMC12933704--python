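"""Exception hierarchy for dmdock."""


class DmdockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DmdockError):
    """A structure or molecule file could not be parsed."""


class EmptyStructureError(DmdockError):
    """A parsed structure contained no atoms."""


class EmptyPocketError(DmdockError):
    """Pocket extraction produced no atoms."""


class DegeneratePocketError(DmdockError):
    """The pocket is too small or geometrically degenerate for the task."""


class UnderdeterminedError(DmdockError):
    """Not enough independent constraints (e.g. < 3 matched C-alpha atoms,
    or < 4 non-coplanar anchors for multilateration)."""


class ConformerError(DmdockError):
    """3D conformer embedding failed."""


class InputError(DmdockError):
    """Invalid user-supplied input (mismatched atom counts, bad SMILES, ...)."""


class TypedSystemError(DmdockError):
    """Force-field atom typing failed for the system."""


class RefinementError(DmdockError):
    """Force-field refinement produced a non-finite energy."""


class FeatureUnavailableError(DmdockError):
    """An optional external feature (e.g. the Vina hook) is not configured."""
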