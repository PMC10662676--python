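# POETIC personal-recovery coding frame: 6 first-level domains,
# 21 second-level categories.
Purpose and meaning:
  - Meaning of mental illness experiences
  - Paid or voluntary work
  - Quality of life
  - Meaningful life and social roles
Optimism and hope:
  - Belief in possibility of recovery
  - Positive thinking and valuing success
  - Hope-inspiring relationships
  - Having dreams and aspirations
Empowerment:
  - Self-management and personal responsibility
  - Controversial role of medication
  - Control over life
Tensions:
  - Balancing acceptance with ambitions
  - Openness enables support but also stigmatization
  - Ambivalence around (hypo)mania
Identity:
  - Rebuilding positive sense of self
  - Overcoming stigma
  - Dimensions of identity
Connectedness:
  - Support from others
  - Relationships
  - Peer support and support groups
  - Being part of the community
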