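<?xml version="1.0" encoding="utf-8"?>
<KinoveaVideoAnalysis>
  <FormatVersion>1.5</FormatVersion>
  <Producer>Kinovea.0.8.15</Producer>
  <Tracks>
    <Track name="instrument-tip">
      <TrackPointList Count="5">
        <TrackPoint X="100" Y="200" T="0"/>
        <TrackPoint X="110.5" Y="198.5" T="1"/>
        <TrackPoint X="125.25" Y="190" T="2"/>
        <TrackPoint X="130" Y="185.5" T="3"/>
        <TrackPoint X="142.75" Y="180.25" T="4"/>
      </TrackPointList>
    </Track>
  </Tracks>
</KinoveaVideoAnalysis>
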