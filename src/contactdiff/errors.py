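"""Exception hierarchy shared by all contactdiff modules."""


class ContactDiffError(Exception):
    """Base class for all package errors."""


class FormatError(ContactDiffError):
    """A file is readable but does not contain the expected records."""


class StructuralError(ContactDiffError):
    """Topology/trajectory content violates a structural contract
    (atom-count mismatch, missing required atoms, missing chain...)."""


class SelectionError(ContactDiffError):
    """An atom selection matched nothing."""


class EmptySystemError(ContactDiffError):
    """An operation removed every atom from the system."""


class ParameterError(ContactDiffError):
    """An analysis parameter is outside its valid range."""


class CompatibilityError(ContactDiffError):
    """Two objects being combined disagree on shape, residue table or
    provenance parameters."""


class KindError(ContactDiffError):
    """A matrix of the wrong value kind (probability vs mean distance)
    was passed to an operation."""


class MappingError(ContactDiffError):
    """A domain map references residues absent from the topology."""


class ClassificationError(ContactDiffError):
    """A residue name has no entry in the residue-class scheme."""


class GeneratorError(ContactDiffError):
    """A synthetic-ensemble specification fails its geometric safety
    checks (an unplanted pair could fall inside a configured cutoff)."""
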