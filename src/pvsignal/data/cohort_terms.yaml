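# Free-text search terms defining the glioma cohorts.  Matching is
# case-insensitive contiguous-substring over the indication and medical
# history/diagnosis fields.  The strict set is a subset of the broad set.
broad:
  - GLIOMA
  - MALIGNANT GLIOMA
  - GLIOBLASTOMA
  - GLIOBLASTOMA MULTIFORME
  - ASTROCYTOMA
  - ANAPLASTIC ASTROCYTOMA
  - OLIGODENDROGLIOMA
  - ANAPLASTIC OLIGODENDROGLIOMA
strict:
  - MALIGNANT GLIOMA
  - GLIOBLASTOMA
  - GLIOBLASTOMA MULTIFORME
  - ANAPLASTIC ASTROCYTOMA
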