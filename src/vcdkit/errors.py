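"""Exception hierarchy for vcdkit."""


class VCDKitError(Exception):
    """Base class for all vcdkit errors."""


class InputError(VCDKitError):
    """Malformed or inconsistent user input (files, ensembles, tables)."""


class HeterogeneousEnsembleError(InputError):
    """Conformers in one ensemble do not share the same atom identity."""


class LabelCollisionError(InputError):
    """Two conformers in one ensemble carry the same label."""


class IncompatibleStructuresError(InputError):
    """Pairwise operation on conformers with different atom identities."""


class EnergyUnavailableError(InputError):
    """A requested energy field is missing from a conformer."""


class DegenerateGeometryError(VCDKitError):
    """Geometry too degenerate for the requested operation."""


class ZeroSpectrumError(VCDKitError):
    """An operation that needs a nonzero spectrum received an all-zero one."""


class EmptyRegionError(VCDKitError):
    """A requested frequency region does not overlap the spectrum grid."""
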