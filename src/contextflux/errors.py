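"""Exception hierarchy for contextflux.

Every failure mode the pipeline distinguishes gets its own class so callers
can react to (say) a dangling metabolite differently from a malformed file.
"""


class ContextfluxError(Exception):
    """Base class for all package errors."""


class NetworkParseError(ContextfluxError):
    """The input file could not be parsed in the declared format."""


class DanglingMetaboliteError(ContextfluxError):
    """A reaction references a metabolite that is not defined in the network."""


class MissingObjectiveError(ContextfluxError):
    """The declared objective (biomass) reaction id does not resolve."""


class UnknownCompartmentError(ContextfluxError):
    """A metabolite uses a compartment code outside the fixed 8-code set."""


class MalformedGprError(ContextfluxError):
    """A gene-protein-reaction rule string or tree is not well formed."""


class MissingMetaboliteError(ContextfluxError):
    """A demand specification consumes a metabolite absent from the network."""


class UnknownResidueError(ContextfluxError):
    """A protein sequence contains a letter outside the 20 standard codes."""


class FunctionalityFloorInfeasibleError(ContextfluxError):
    """GIMME's required objective floor cannot be attained at all.

    Distinct from a generic LP failure: the parent network itself cannot
    carry the required fraction of the optimum under the given constraints.
    """


class SamplingError(ContextfluxError):
    """The flux sampler was given an infeasible or degenerate model."""


class ConfigurationError(ContextfluxError):
    """A pipeline configuration value or path is invalid."""
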