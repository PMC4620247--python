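# Data-collection-set schema for the ACS/CHF surveillance use case:
# the published sample of schema items, annotated with SDTM data elements
# and the MedDRA preferred-term codes their condition entries must match.
content_model: CIM-RDF
items:
  - name: Sex
    elements:
      - element: "SDTM:DM.DMSEX"
    derivation:
      function: VALUE

  - name: DateOfACS
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10051592"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: FIRST_DATE

  - name: DateOfAMI
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10000891"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: FIRST_DATE

  - name: DateOfUnstableAngina
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10002388"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: FIRST_DATE

  - name: CHFBeforeACS
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10007559"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: EXISTS_BEFORE
      index: DateOfACS

  - name: CHFAfterACS
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10007559"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: EXISTS_AFTER
      index: DateOfACS
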