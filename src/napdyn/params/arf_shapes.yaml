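# Exponential-to-plateau decline shapes for per-ARF nuclear fold-change
# time courses:  fc(t) = plateau + (1 - plateau) * exp(-t / tau_h).
#
# Qualitative behaviour encoded: MpARF1 and MpARF2 decline post-germination,
# MpARF3 stays flat, and MpARF2 reaches undetectability earlier than MpARF1
# (smaller tau_h and near-zero plateau).  Numeric values are free parameters
# of the generator, not measurements.
ARF1:
  plateau: 0.15
  tau_h: 8.0
ARF2:
  plateau: 0.005
  tau_h: 3.0
ARF3:
  plateau: 1.0   # flat control: fc identically 1
  tau_h: 1.0
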