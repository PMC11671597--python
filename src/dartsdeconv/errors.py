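"""Exception hierarchy for the dartsdeconv package."""


class DartsDeconvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DartsDeconvError):
    """Invalid generator or run configuration."""


class EvidenceError(DartsDeconvError):
    """Peptide evidence inconsistent with the protein sequences."""


class ProteinLookupError(DartsDeconvError, KeyError):
    """Referenced protein id not present in the proteome."""


class ResidueLookupError(DartsDeconvError, KeyError):
    """Referenced residue id not present in the structure."""


class FitError(DartsDeconvError):
    """Nonlinear fit failed, diverged, or the data are underdetermined."""


class UnsupportedMutationError(DartsDeconvError):
    """Alanine mutation requested for GLY, PRO or ALA."""


class SingularityError(DartsDeconvError):
    """Pairwise energy requested at zero interatomic distance."""
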