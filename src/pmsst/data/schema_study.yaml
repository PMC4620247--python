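# Full study schema: the published sample items plus the derived follow-up
# anchors (STARTDATE = ACS + 30 days; LASTDATE = min of death, transfer-out,
# study end), the incident-CHF event date, and the windowed calculations
# (mean systolic BP / HbA1c over the year before ACS, last weight before ACS).
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

  - name: DeathDate
    elements:
      - element: "SDTM:DM.DTHDTC"
    derivation:
      function: VALUE

  - name: TransferOutDate
    elements:
      - element: "SDTM:DM.RFPENDTC"
    derivation:
      function: VALUE

  - name: STARTDATE
    derivation:
      function: DATE_OFFSET
      index: DateOfACS
      offset_days: 30

  - name: LASTDATE
    derivation:
      function: MIN_DATE
      candidates: [DeathDate, TransferOutDate]
      constants: ["2011-12-31"]

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
      index: STARTDATE

  - name: FirstCHFDate
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10007559"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: FIRST_DATE

  - name: T2DBeforeACS
    elements:
      - element: "SDTM:MH.MHPTCD"
        code: "10067585"
        system: MedDRA
      - element: "SDTM:MH.MHSTDTC"
    derivation:
      function: EXISTS_BEFORE
      index: DateOfACS

  - name: MeanSysBP1YBeforeACS
    elements:
      - element: "SDTM:VS.VSTESTCD"
        code: "SYSBP"
        system: LOCAL-OBS
      - element: "SDTM:VS.VSORRES"
      - element: "SDTM:VS.VSDTC"
    derivation:
      function: MEAN_IN_WINDOW
      index: DateOfACS
      window_days: 365

  - name: MeanHbA1c1YBeforeACS
    elements:
      - element: "SDTM:VS.VSTESTCD"
        code: "HBA1C"
        system: LOCAL-OBS
      - element: "SDTM:VS.VSORRES"
      - element: "SDTM:VS.VSDTC"
    derivation:
      function: MEAN_IN_WINDOW
      index: DateOfACS
      window_days: 365

  - name: LastWeightBeforeACS
    elements:
      - element: "SDTM:VS.VSTESTCD"
        code: "WEIGHT"
        system: LOCAL-OBS
      - element: "SDTM:VS.VSORRES"
      - element: "SDTM:VS.VSDTC"
    derivation:
      function: LAST_VALUE_BEFORE
      index: DateOfACS
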