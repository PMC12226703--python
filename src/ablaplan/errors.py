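"""Package-level exceptions."""


class AblaplanError(Exception):
    """Base class for planner errors."""


class InvalidEnvironmentError(AblaplanError):
    """The anatomy/environment cannot support planning (e.g. empty treatment volume)."""


class PlanningInfeasibleError(AblaplanError):
    """No admissible entry region or no feasible plan exists for the request."""
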