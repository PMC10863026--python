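{"visit_id":"V000","oird":false}
{"visit_id":"V001","oird":false}
{"visit_id":"V002","oird":false}
{"visit_id":"V003","oird":false}
{"visit_id":"V004","oird":false}
{"visit_id":"V005","oird":false}
{"visit_id":"V006","oird":false}
{"visit_id":"V007","oird":false}
{"visit_id":"V008","oird":false}
{"visit_id":"V009","oird":false}
{"visit_id":"V010","oird":false}
{"visit_id":"V011","oird":false}
{"visit_id":"V012","oird":false}
{"visit_id":"V013","oird":false}
{"visit_id":"V014","oird":false}
{"visit_id":"V015","oird":false}
{"visit_id":"V016","oird":false}
{"visit_id":"V017","oird":false}
{"visit_id":"V018","oird":false}
{"visit_id":"V019","oird":false}
{"visit_id":"V020","oird":false}
{"visit_id":"V021","oird":false}
{"visit_id":"V022","oird":false}
{"visit_id":"V023","oird":false}
{"visit_id":"V024","oird":false}
{"visit_id":"V025","oird":false}
{"visit_id":"V026","oird":false}
{"visit_id":"V027","oird":false}
{"visit_id":"V028","oird":false}
{"visit_id":"V029","oird":false}
{"visit_id":"V030","oird":false}
{"visit_id":"V031","oird":false}
{"visit_id":"V032","oird":false}
{"visit_id":"V033","oird":false}
{"visit_id":"V034","oird":false}
{"visit_id":"V035","oird":false}
{"visit_id":"V036","oird":false}
{"visit_id":"V037","oird":false}
{"visit_id":"V038","oird":false}
{"visit_id":"V039","oird":false}
{"visit_id":"V040","oird":false}
{"visit_id":"V041","oird":false}
{"visit_id":"V042","oird":false}
{"visit_id":"V043","oird":false}
{"visit_id":"V044","oird":false}
{"visit_id":"V045","oird":false}
{"visit_id":"V046","oird":true}
{"visit_id":"V047","oird":false}
{"visit_id":"V048","oird":false}
{"visit_id":"V049","oird":false}
{"visit_id":"V050","oird":false}
{"visit_id":"V051","oird":false}
{"visit_id":"V052","oird":false}
{"visit_id":"V053","oird":false}
{"visit_id":"V054","oird":false}
{"visit_id":"V055","oird":false}
{"visit_id":"V056","oird":false}
{"visit_id":"V057","oird":false}
{"visit_id":"V058","oird":false}
{"visit_id":"V059","oird":false}
{"visit_id":"V060","oird":false}
{"visit_id":"V061","oird":false}
{"visit_id":"V062","oird":false}
{"visit_id":"V063","oird":false}
{"visit_id":"V064","oird":false}
{"visit_id":"V065","oird":false}
{"visit_id":"V066","oird":false}
{"visit_id":"V067","oird":false}
{"visit_id":"V068","oird":false}
{"visit_id":"V069","oird":false}
{"visit_id":"V070","oird":false}
{"visit_id":"V071","oird":false}
{"visit_id":"V072","oird":false}
{"visit_id":"V073","oird":false}
{"visit_id":"V074","oird":false}
{"visit_id":"V075","oird":false}
{"visit_id":"V076","oird":false}
{"visit_id":"V077","oird":false}
{"visit_id":"V078","oird":false}
{"visit_id":"V079","oird":false}
{"visit_id":"V080","oird":false}
{"visit_id":"V081","oird":false}
{"visit_id":"V082","oird":false}
{"visit_id":"V083","oird":false}
{"visit_id":"V084","oird":false}
{"visit_id":"V085","oird":false}
{"visit_id":"V086","oird":false}
{"visit_id":"V087","oird":false}
{"visit_id":"V088","oird":false}
{"visit_id":"V089","oird":false}
{"visit_id":"V090","oird":false}
{"visit_id":"V091","oird":false}
{"visit_id":"V092","oird":false}
{"visit_id":"V093","oird":false}
{"visit_id":"V094","oird":false}
{"visit_id":"V095","oird":false}
{"visit_id":"V096","oird":false}
{"visit_id":"V097","oird":false}
{"visit_id":"V098","oird":false}
{"visit_id":"V099","oird":false}
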