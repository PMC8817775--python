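attributes:
  - name: provider
    code: c
    reference: family member
    levels: [family member, community health worker, expert client]
    level_codes:
      community health worker: chw
      expert client: expert
  - name: location
    code: l
    reference: workplace
    levels: [workplace, home]
    level_codes:
      home: home
  - name: support
    code: s
    reference: SMS
    levels: [SMS, phone call, travel voucher]
    level_codes:
      phone call: phcall
      travel voucher: tvouch
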