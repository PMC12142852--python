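"""Generate a scenario-specific configuration template.

Only the fields mandatory for the chosen data levels appear; a study being
extended (samples already deposited) is asked for accessions instead of
sample metadata.
"""

from mgbroker import Level, SubmissionScenario, make_template

print("--- submitting samples + reads from scratch ---")
print(make_template(SubmissionScenario({Level.SAMPLES, Level.READS})))

print("--- adding bins to an already-deposited study ---")
print(make_template(SubmissionScenario(
    {Level.BINS},
    preexisting={Level.SAMPLES: ("ERS0000001", "ERS0000002"),
                 Level.ASSEMBLY: ("ERZ0000001",)})))
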