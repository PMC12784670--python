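# Composite endpoint definitions as MedDRA preferred-term (PT) lists.
# A report counts once toward an endpoint when >= 1 of its reaction PTs
# is in the endpoint's list.  The three shipped sets are pairwise
# disjoint.  Lists are user-extensible approximations of clinically
# coherent PT groupings (venous thromboembolism, CNS bleeding, GI
# bleeding); no MedDRA hierarchy expansion is performed.
VTE:
  - DEEP VEIN THROMBOSIS
  - PULMONARY EMBOLISM
  - VENOUS THROMBOSIS
  - EMBOLISM VENOUS
  - EMBOLISM
  - THROMBOSIS
  - PULMONARY THROMBOSIS
  - PELVIC VENOUS THROMBOSIS
  - JUGULAR VEIN THROMBOSIS
  - SUBCLAVIAN VEIN THROMBOSIS
  - VENA CAVA THROMBOSIS
  - VENOUS THROMBOSIS LIMB
CNS_BLEED:
  - INTRACRANIAL HAEMORRHAGE
  - HAEMORRHAGE INTRACRANIAL
  - CEREBRAL HAEMORRHAGE
  - INTRACEREBRAL HAEMATOMA
  - CEREBRAL HAEMATOMA
  - SUBARACHNOID HAEMORRHAGE
  - SUBDURAL HAEMATOMA
  - SUBDURAL HAEMORRHAGE
  - HAEMORRHAGIC STROKE
  - CEREBELLAR HAEMORRHAGE
  - BRAIN STEM HAEMORRHAGE
  - BASAL GANGLIA HAEMORRHAGE
GI_BLEED:
  - GASTROINTESTINAL HAEMORRHAGE
  - UPPER GASTROINTESTINAL HAEMORRHAGE
  - LOWER GASTROINTESTINAL HAEMORRHAGE
  - HAEMATEMESIS
  - MELAENA
  - RECTAL HAEMORRHAGE
  - GASTRIC HAEMORRHAGE
  - DUODENAL ULCER HAEMORRHAGE
  - GASTRIC ULCER HAEMORRHAGE
  - HAEMATOCHEZIA
  - SMALL INTESTINAL HAEMORRHAGE
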