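# Versioned code lists for register-based suicidality ascertainment (ICD-10).
#
# Suicide: underlying cause of death X60-X84 (intentional self-harm) or
# Y87.0 (sequelae of intentional self-harm); a registered manner of death of
# "suicide" also qualifies regardless of code (handled in code, not here).
#
# Probable suicide attempt, any of four definitions on a hospital contact:
#   a) main or supplementary diagnosis X60-X84, or a reason-of-contact
#      recording of "suicide attempt";
#   b) main diagnosis of accidental intoxication with weak analgesics,
#      antiepileptics, sleeping pills, antiparkinsonian drugs, psychotropics
#      or carbon monoxide: T39, T40 except T40.1 (heroin), T42, T43, T58;
#   c) main psychiatric diagnosis (F00-F99) with a sub-diagnosis of
#      intoxication with drugs and biological substances except alcohol:
#      T36-T50, T52-T60;
#   d) main psychiatric diagnosis (F00-F99) with a sub-diagnosis of injury
#      to the lower forearm: S51, S55, S59, S61, S65, S69.
version: "1.0"
suicide_cause:
  includes: ["X60-X84", "Y870"]
attempt_definitions:
  a:
    main_or_sub:
      includes: ["X60-X84"]
    reason_of_contact: true
  b:
    main:
      includes: ["T39", "T40", "T42", "T43", "T58"]
      excludes: ["T401"]
  c:
    main:
      includes: ["F00-F99"]
    sub:
      includes: ["T36-T50", "T52-T60"]
  d:
    main:
      includes: ["F00-F99"]
    sub:
      includes: ["S51", "S55", "S59", "S61", "S65", "S69"]
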