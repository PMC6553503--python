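(TFS001:1.0)FAMS001;
(TFS002:1.0)FAMS002;
(TFS003:1.0)FAMS003;
(TFS004:1.0)FAMS004;
(TFS005:1.0)FAMS005;
(TFS006:1.0)FAMS006;
(TFS007:1.0)FAMS007;
(TFS008:1.0)FAMS008;
(TFS009:1.0)FAMS009;
(TFS010:1.0)FAMS010;
(TFS011:1.0)FAMS011;
(TFS012:1.0)FAMS012;
(TFS013:1.0)FAMS013;
(TFS014:1.0)FAMS014;
(TFS015:1.0)FAMS015;
(TFS016:1.0)FAMS016;
(TFS017:1.0)FAMS017;
(TFS018:1.0)FAMS018;
(TFS019:1.0)FAMS019;
(TFS020:1.0)FAMS020;
(TFS021:1.0)FAMS021;
(TFS022:1.0)FAMS022;
(TFS023:1.0)FAMS023;
(TFS024:1.0)FAMS024;
(TFS025:1.0)FAMS025;
(TFS026:1.0)FAMS026;
(TFS027:1.0)FAMS027;
(TFS028:1.0)FAMS028;
(TFS029:1.0)FAMS029;
(TFS030:1.0)FAMS030;
(TFS031:1.0)FAMS031;
(TFS032:1.0)FAMS032;
(TFS033:1.0)FAMS033;
(TFS034:1.0)FAMS034;
(TFS035:1.0)FAMS035;
(TFS036:1.0)FAMS036;
(TFS037:1.0)FAMS037;
(TFS038:1.0)FAMS038;
(TFS039:1.0)FAMS039;
(TFN001:0.5,PARN001:0.5)FAMN001;
(TFN002:0.5,PARN002:0.5)FAMN002;
(TFN003:0.5,PARN003:0.5)FAMN003;
(TFN004:0.5,PARN004:0.5)FAMN004;
(TFN005:0.5,PARN005:0.5)FAMN005;
(TFN006:0.5,PARN006:0.5)FAMN006;
(TFN007:0.5,PARN007:0.5)FAMN007;
(TFN008:0.5,PARN008:0.5)FAMN008;
(TFN009:0.5,PARN009:0.5)FAMN009;
(TFN010:0.5,PARN010:0.5)FAMN010;
(TFN011:0.5,PARN011:0.5)FAMN011;
(TFN012:0.5,PARN012:0.5)FAMN012;
(TFN013:0.5,PARN013:0.5)FAMN013;
(TFN014:0.5,PARN014:0.5)FAMN014;
(Ehd3:0.5,LOC_Os01g66070:0.5)PHD;
(LOC_Os09g31310:0.5,LOC_Os02g48650:0.5)GNAT;
(OsMADS8:0.5,OsMADS7:0.5)MADS;
(TFP001:0.5,PARP001:0.5)FAMP001;
(TFP002:0.5,PARP002:0.5)FAMP002;
(TFP003:0.5,PARP003:0.5)FAMP003;
(TFP004:0.5,PARP004:0.5)FAMP004;
(TFP005:0.5,PARP005:0.5)FAMP005;
(TFP006:0.5,PARP006:0.5)FAMP006;
(TFP007:0.5,PARP007:0.5)FAMP007;
(TFP008:0.5,PARP008:0.5)FAMP008;
(TFP009:0.5,PARP009:0.5)FAMP009;
(TFP010:0.5,PARP010:0.5)FAMP010;
(TFP011:0.5,PARP011:0.5)FAMP011;
(TFP012:0.5,PARP012:0.5)FAMP012;
(TFP013:0.5,PARP013:0.5)FAMP013;
(TFP014:0.5,PARP014:0.5)FAMP014;
(TFP015:0.5,PARP015:0.5)FAMP015;
(TFP016:0.5,PARP016:0.5)FAMP016;
(TFP017:0.5,PARP017:0.5)FAMP017;
(TFP018:0.5,PARP018:0.5)FAMP018;
(TFP019:0.5,PARP019:0.5)FAMP019;
(TFP020:0.5,PARP020:0.5)FAMP020;
(TFP021:0.5,PARP021:0.5)FAMP021;
(TFP022:0.5,PARP022:0.5)FAMP022;
(TFP023:0.5,PARP023:0.5)FAMP023;
(TFP024:0.5,PARP024:0.5)FAMP024;
(TFP025:0.5,PARP025:0.5)FAMP025;
(TFP026:0.5,PARP026:0.5)FAMP026;
(TFP027:0.5,PARP027:0.5)FAMP027;
(TFP028:0.5,PARP028:0.5)FAMP028;
(TFP029:0.5,PARP029:0.5)FAMP029;
(TFP030:0.5,PARP030:0.5)FAMP030;
(TFP031:0.5,PARP031:0.5)FAMP031;
(TFP032:0.5,PARP032:0.5)FAMP032;
(TFP033:0.5,PARP033:0.5)FAMP033;
(TFP034:0.5,PARP034:0.5)FAMP034;
(TFP035:0.5,PARP035:0.5)FAMP035;
(TFP036:0.5,PARP036:0.5)FAMP036;
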